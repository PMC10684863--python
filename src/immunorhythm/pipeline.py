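"""End-to-end orchestration: cohort -> rhythms -> probabilities ->
signatures -> networks, with a reproducible report bundle.

``run_pipeline`` is deterministic given config + seed: it writes every
stage's tables under the output directory together with a manifest
(stage, output files, SHA-256 hashes), a machine-readable warnings file
and a resolved-config snapshot sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import networks as net
from . import probability, rhythms, signatures
from .cohort import DEFAULT_SCHEME, CohortTable, group_counts, read_cohort, write_cohort
from .simulate import generate_cohort, null_params, study_params

__all__ = ["PipelineConfig", "run_pipeline", "ALL_STAGES"]

log = logging.getLogger("immunorhythm")

ALL_STAGES = ("cohort", "rhythms", "probabilities", "signatures", "networks")

PRESETS = {"study": study_params, "null": null_params}


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run."""

    input: str | None = None          # CSV path; None -> use preset
    preset: str = "study"
    seed: int = 0
    outdir: str = "immunorhythm_out"
    strata: tuple[str, ...] = ("ALL", "male", "female")
    percentile: float = 75.0          # dichotomization percentile
    alpha: float = 0.05               # significance level everywhere
    weak_threshold: float = 0.1       # |rho| band edges
    strong_threshold: float = 0.67
    formats: tuple[str, ...] = ("edge-csv", "graphml")
    adjust: bool = False              # Benjamini-Hochberg on comparisons

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0.0 < self.percentile < 100.0:
            raise ValueError("percentile must lie in (0, 100)")
        if not (0.0 < self.weak_threshold < self.strong_threshold < 1.0):
            raise ValueError("need 0 < weak_threshold < strong_threshold < 1")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")
        if self.input is None and self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; "
                             f"available: {sorted(PRESETS)}")
        for s in self.strata:
            if s not in ("ALL", "male", "female"):
                raise ValueError(f"unknown stratum {s!r}")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load YAML or JSON config; keyword overrides win over file keys."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("strata", "formats"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        # JSON-canonical (tuples become lists) so manifests round-trip
        return json.loads(json.dumps(dataclasses.asdict(self)))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_cohort(config: PipelineConfig) -> CohortTable:
    if config.input is not None:
        return read_cohort(config.input)
    params = PRESETS[config.preset](seed=config.seed)
    return generate_cohort(params, seed=config.seed)


def run_pipeline(config: PipelineConfig,
                 stages: tuple[str, ...] = ALL_STAGES) -> dict:
    """Run the requested stages and write the report bundle.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    config.validate()
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {"config": config.to_dict(), "stages": {}}
    caught: list[dict] = []

    def record(stage: str, paths: list[Path]) -> None:
        manifest["stages"][stage] = {
            str(p.relative_to(outdir)): _sha256(p) for p in sorted(paths)
        }
        log.info("stage %s: wrote %d file(s)", stage, len(paths))

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        cohort = _load_cohort(config)

        if "cohort" in stages:
            paths = []
            p = outdir / "cohort.csv"
            write_cohort(cohort, p)
            paths.append(p)
            p = outdir / "group_counts.csv"
            group_counts(cohort, by_sex=True).to_csv(p)
            paths.append(p)
            p = outdir / "validation.jsonl"
            p.write_text(cohort.report.to_json_lines() + "\n"
                         if cohort.report else "")
            paths.append(p)
            record("cohort", paths)

        if "rhythms" in stages:
            paths = []
            frames = []
            for s in config.strata:
                res = rhythms.adjacent_comparisons(cohort, s,
                                                   adjust=config.adjust)
                frames.append(rhythms.comparisons_to_frame(res))
                p = outdir / f"significance_{s}.txt"
                p.write_text(rhythms.significance_table(res).to_string() + "\n")
                paths.append(p)
            res = rhythms.sex_matched_comparisons(cohort, adjust=config.adjust)
            frames.append(rhythms.comparisons_to_frame(res))
            import pandas as pd
            p = outdir / "comparisons.csv"
            pd.concat(frames, ignore_index=True).to_csv(p, index=False)
            paths.append(p)
            record("rhythms", paths)

        if "probabilities" in stages:
            import pandas as pd
            fits = pd.concat(
                [probability.fit_stratum(cohort, s, config.percentile)
                 for s in config.strata], ignore_index=True)
            curves = probability.probability_curves(fits)
            p1 = outdir / "logistic_fits.csv"
            fits.to_csv(p1, index=False)
            p2 = outdir / "probability_curves.csv"
            curves.to_csv(p2, index=False)
            record("probabilities", [p1, p2])

        if "signatures" in stages:
            paths = []
            for s in config.strata:
                sig = signatures.signature_proportions(cohort, stratum=s)
                heat = signatures.equalize_heatmap(sig)
                p = outdir / f"signature_{s}.csv"
                sig.values.to_csv(p)
                paths.append(p)
                p = outdir / f"heatmap_{s}.csv"
                heat.values.to_csv(p)
                paths.append(p)
                p = outdir / f"radar_{s}.csv"
                signatures.radar_table(sig).to_csv(p, index=False)
                paths.append(p)
            record("signatures", paths)

        if "networks" in stages:
            paths = []
            for s in config.strata:
                nets = {
                    g: net.build_group_network(
                        cohort, g, s, alpha=config.alpha,
                        strong=config.strong_threshold,
                        weak=config.weak_threshold)
                    for g in cohort.scheme.labels
                }
                nets = {g: e for g, e in nets.items() if e}
                if len(nets) < 2:
                    warnings.warn(f"stratum {s}: fewer than 2 non-empty "
                                  "group networks; skipped")
                    continue
                summary = net.classify_edges(nets)
                paths += net.export_network(nets, summary,
                                            outdir / f"networks_{s}",
                                            formats=config.formats)
            record("networks", paths)

        caught = [{"category": type(w.message).__name__,
                   "message": str(w.message)} for w in wlist]

    (outdir / "warnings.jsonl").write_text(
        "\n".join(json.dumps(w) for w in caught) + ("\n" if caught else ""))
    (outdir / "config.resolved.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True))
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))
    return manifest
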