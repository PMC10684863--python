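"""Per-age-group Spearman correlation networks over the 12-phenotype panel.

Within each age group (optionally one sex), all 66 unordered phenotype
pairs are tested by Spearman rank correlation; edges with p < 0.05 form
the group's network.  Edge strength follows the conventional banding:
strong at |rho| >= 0.67, weak/moderate at 0.1 <= |rho| < 0.67 (edges
significant at large n with |rho| < 0.1 are retained but flagged
sub-threshold-weak).  Across groups, edges significant in every group
with a consistent sign are "common" (conserved) axes; edges significant
in exactly one group are "selective" to it.

Note that compositional closure (lineage frequencies sum to 100%)
induces structural negative correlation among same-lineage pairs, so
within-lineage edges are expected even under a null generator; null
calibration of false positives should be read on cross-lineage pairs.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable
from .panel import CLUSTER_FAMILIES, PHENOTYPES, lineage_of

__all__ = [
    "SpearmanResult",
    "EdgeRecord",
    "NetworkSummary",
    "spearman",
    "spearman_matrix",
    "build_group_network",
    "classify_edges",
    "export_network",
    "STRONG_THRESHOLD",
    "WEAK_THRESHOLD",
]

STRONG_THRESHOLD = 0.67
WEAK_THRESHOLD = 0.1
EXACT_N_LIMIT = 10


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p: float
    method: str  # 't' or 'exact'


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p over all n! orderings of the y midranks."""
    n = rx.size
    rxc = rx - rx.mean()
    denom = np.sqrt((rxc ** 2).sum())
    count = 0
    total = 0
    chunk: list[tuple[float, ...]] = []
    ry_c = ry - ry.mean()
    sy = np.sqrt((ry_c ** 2).sum())
    thresh = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(ry):
        chunk.append(perm)
        if len(chunk) == 100_000:
            arr = np.asarray(chunk)
            rhos = ((arr - arr.mean(axis=1, keepdims=True)) @ rxc) / (denom * sy)
            count += int((np.abs(rhos) >= thresh).sum())
            total += len(chunk)
            chunk = []
    if chunk:
        arr = np.asarray(chunk)
        rhos = ((arr - arr.mean(axis=1, keepdims=True)) @ rxc) / (denom * sy)
        count += int((np.abs(rhos) >= thresh).sum())
        total += len(chunk)
    return count / total


def spearman(x, y, mode: str = "auto") -> SpearmanResult:
    """Spearman rank correlation with two-sided p.

    rho is the Pearson correlation of midranks.  The p-value uses the
    t-approximation t = rho * sqrt((n-2) / (1-rho^2)) by default; exact
    permutation enumeration is used for n <= 8 in ``auto`` mode and
    available up to n <= 10 with ``mode='exact'``.  Constant input yields
    undefined rho (NaN) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if mode not in ("auto", "t", "exact"):
        raise ValueError(f"unknown mode {mode!r}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant series: Spearman rho undefined", stacklevel=2)
        return SpearmanResult(np.nan, np.nan, "degenerate")

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    use_exact = (mode == "exact") or (mode == "auto" and n <= 8)
    if use_exact:
        if n > EXACT_N_LIMIT:
            raise ValueError(f"exact mode limited to n <= {EXACT_N_LIMIT}")
        return SpearmanResult(rho, _exact_spearman_p(rx, ry, rho), "exact")

    if abs(rho) >= 1.0:
        return SpearmanResult(rho, 0.0, "t")
    t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return SpearmanResult(rho, min(p, 1.0), "t")


def spearman_matrix(freqs: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full rho and t-approximation p matrices over the panel columns
    (equal to pairwise :func:`spearman` in ``t`` mode)."""
    cols = list(freqs.columns)
    res = stats.spearmanr(freqs.to_numpy())
    rho = pd.DataFrame(np.atleast_2d(res.statistic), index=cols, columns=cols)
    n = len(freqs)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = rho.to_numpy()
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r ** 2, 1e-300, None))
        p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    pm = pd.DataFrame(np.minimum(p, 1.0), index=cols, columns=cols)
    return rho, pm


def _strength(rho: float, strong: float = STRONG_THRESHOLD,
              weak: float = WEAK_THRESHOLD) -> str:
    a = abs(rho)
    if a >= strong:
        return "strong"
    if a >= weak:
        return "weak_moderate"
    return "sub_threshold_weak"


@dataclass(frozen=True)
class EdgeRecord:
    source: str
    target: str
    group: str
    rho: float
    p: float
    sign: str        # positive / negative
    strength: str    # strong / weak_moderate / sub_threshold_weak
    significant: bool

    @property
    def pair(self) -> tuple[str, str]:
        return (self.source, self.target)

    @property
    def cross_lineage(self) -> bool:
        return lineage_of(self.source) != lineage_of(self.target)


def build_group_network(cohort: CohortTable, group: str,
                        stratum: str = "ALL",
                        alpha: float = 0.05,
                        strong: float = STRONG_THRESHOLD,
                        weak: float = WEAK_THRESHOLD) -> list[EdgeRecord]:
    """Test all 66 phenotype pairs within one age group.

    Returns one EdgeRecord per testable pair with the significance flag
    set at ``p < alpha``; groups with fewer than 4 subjects yield an
    empty list with a warning, and constant phenotypes have their pairs
    omitted with a warning.
    """
    df = cohort.frequencies(group, stratum)
    if len(df) < 4:
        warnings.warn(f"group {group} (stratum {stratum}) has n={len(df)} "
                      "< 4; empty network", stacklevel=2)
        return []
    constant = [c for c in df.columns if df[c].nunique() == 1]
    if constant:
        warnings.warn(f"constant phenotype(s) {constant} in {group}: "
                      "their edges are omitted", stacklevel=2)
    rho, pmat = spearman_matrix(df)
    edges = []
    for a, b in itertools.combinations(PHENOTYPES, 2):
        if a in constant or b in constant:
            continue
        r, p = float(rho.loc[a, b]), float(pmat.loc[a, b])
        edges.append(EdgeRecord(
            source=a, target=b, group=group, rho=r, p=p,
            sign="positive" if r >= 0 else "negative",
            strength=_strength(r, strong, weak), significant=bool(p < alpha),
        ))
    return edges


@dataclass
class NetworkSummary:
    """Cross-group bookkeeping of significant correlation axes."""

    total: dict[str, int]                      # significant edges per group
    selective: dict[str, list[tuple[str, str]]]  # significant in this group only
    common: list[tuple[str, str]]              # significant in all groups (same sign)
    strong_nodes: dict[str, list[str]]         # nodes with >= 1 strong significant edge
    strong_edge_count: dict[str, dict[str, int]]  # per group, per node
    cluster_contribution: dict[str, dict[str, int]]  # per group, per family
    sign_consistent_common: bool = True
    groups: list[str] = field(default_factory=list)

    @property
    def selective_counts(self) -> dict[str, int]:
        return {g: len(v) for g, v in self.selective.items()}

    def to_json(self) -> str:
        return json.dumps({
            "groups": self.groups,
            "total": self.total,
            "selective_counts": self.selective_counts,
            "selective": {g: [list(p) for p in v]
                          for g, v in self.selective.items()},
            "common": [list(p) for p in self.common],
            "n_common": len(self.common),
            "strong_nodes": self.strong_nodes,
            "cluster_contribution": self.cluster_contribution,
        }, indent=2)


def classify_edges(networks: dict[str, list[EdgeRecord]],
                   sign_consistent_common: bool = True) -> NetworkSummary:
    """Classify edges across group networks into common (conserved) and
    group-selective axes.

    Common axes are significant in every group — with the same sign
    unless ``sign_consistent_common=False``.  Selective axes are
    significant in exactly one group.  The two sets are disjoint by
    construction whenever there is more than one group.
    """
    groups = list(networks)
    if len(groups) < 2:
        raise ValueError("need at least two group networks to classify")

    sig_by_pair: dict[tuple[str, str], dict[str, str]] = {}
    for g, edges in networks.items():
        for e in edges:
            if e.significant:
                sig_by_pair.setdefault(e.pair, {})[g] = e.sign

    common = []
    selective: dict[str, list[tuple[str, str]]] = {g: [] for g in groups}
    for pair, where in sig_by_pair.items():
        if len(where) == len(groups):
            if not sign_consistent_common or len(set(where.values())) == 1:
                common.append(pair)
        elif len(where) == 1:
            selective[next(iter(where))].append(pair)

    total = {g: sum(e.significant for e in networks[g]) for g in groups}
    strong_edge_count: dict[str, dict[str, int]] = {}
    strong_nodes: dict[str, list[str]] = {}
    contribution: dict[str, dict[str, int]] = {}
    for g, edges in networks.items():
        counts = {p: 0 for p in PHENOTYPES}
        fam = {f: 0 for f in sorted(set(CLUSTER_FAMILIES.values()))}
        for e in edges:
            if not e.significant:
                continue
            fam[CLUSTER_FAMILIES[e.source]] += 1
            fam[CLUSTER_FAMILIES[e.target]] += 1
            if e.strength == "strong":
                counts[e.source] += 1
                counts[e.target] += 1
        strong_edge_count[g] = counts
        strong_nodes[g] = [p for p, c in counts.items() if c >= 1]
        contribution[g] = fam

    return NetworkSummary(
        total=total, selective=selective, common=sorted(common),
        strong_nodes=strong_nodes, strong_edge_count=strong_edge_count,
        cluster_contribution=contribution,
        sign_consistent_common=sign_consistent_common, groups=groups,
    )


def edges_to_frame(networks: dict[str, list[EdgeRecord]],
                   summary: NetworkSummary | None = None) -> pd.DataFrame:
    """Tidy edge list over all groups with the selective/common tag."""
    tags = {}
    if summary is not None:
        for pair in summary.common:
            tags[pair] = "common"
        for g, pairs in summary.selective.items():
            for pair in pairs:
                tags[(pair, g)] = "selective"
    rows = []
    for g, edges in networks.items():
        for e in edges:
            tag = ""
            if summary is not None:
                if e.pair in summary.common:
                    tag = "common"
                elif e.pair in summary.selective.get(g, []):
                    tag = "selective"
            rows.append({
                "group": g, "source": e.source, "target": e.target,
                "rho": e.rho, "p": e.p, "sign": e.sign,
                "strength": e.strength, "significant": e.significant,
                "tag": tag,
            })
    cols = ["group", "source", "target", "rho", "p", "sign", "strength",
            "significant", "tag"]
    return pd.DataFrame(rows, columns=cols)


def _group_graph(edges: list[EdgeRecord], group: str,
                 summary: NetworkSummary | None) -> nx.Graph:
    G = nx.Graph(name=group)
    strong = summary.strong_nodes.get(group, []) if summary else []
    for p in PHENOTYPES:
        G.add_node(p, family=CLUSTER_FAMILIES[p],
                   strong_node=p in strong)
    for e in edges:
        if not e.significant:
            continue
        tag = ""
        if summary is not None:
            if e.pair in summary.common:
                tag = "common"
            elif e.pair in summary.selective.get(group, []):
                tag = "selective"
        G.add_edge(e.source, e.target, rho=e.rho, p=e.p, sign=e.sign,
                   strength=e.strength, tag=tag)
    return G


def export_network(networks: dict[str, list[EdgeRecord]],
                   summary: NetworkSummary, outdir: str | Path,
                   formats: tuple[str, ...] = ("edge-csv",)) -> list[Path]:
    """Write per-group networks plus a conserved-axes file.

    Formats: ``edge-csv`` (tidy CSV), ``sif`` (Cytoscape simple
    interaction, one significant edge per line), ``graphml`` (full edge
    and node attributes; round-trips through networkx).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    known = {"edge-csv", "sif", "graphml"}
    bad = set(formats) - known
    if bad:
        raise ValueError(f"unknown format(s) {sorted(bad)}; known: {sorted(known)}")
    written: list[Path] = []
    frame = edges_to_frame(networks, summary)
    for fmt in formats:
        if fmt == "edge-csv":
            for g in networks:
                path = outdir / f"network_{g}.csv"
                frame[frame["group"] == g].to_csv(path, index=False)
                written.append(path)
        elif fmt == "sif":
            for g, edges in networks.items():
                path = outdir / f"network_{g}.sif"
                lines = [f"{e.source}\t{e.sign}_corr\t{e.target}"
                         for e in edges if e.significant]
                path.write_text("\n".join(lines) + ("\n" if lines else ""))
                written.append(path)
        elif fmt == "graphml":
            for g, edges in networks.items():
                path = outdir / f"network_{g}.graphml"
                nx.write_graphml(_group_graph(edges, g, summary), path)
                written.append(path)
    conserved = outdir / "conserved_axes.csv"
    pd.DataFrame([{"source": a, "target": b} for a, b in summary.common]
                 ).to_csv(conserved, index=False)
    written.append(conserved)
    (outdir / "network_summary.json").write_text(summary.to_json())
    written.append(outdir / "network_summary.json")
    return written
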