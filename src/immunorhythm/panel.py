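"""The twelve-phenotype memory T/B-cell panel.

Each lymphocyte lineage (CD4+ T, CD8+ T, CD19+ B) is gated into four
mutually exclusive differentiation phenotypes, so the four frequencies
within a lineage are compositional: they sum to 100% of gated cells.

T-cell phenotypes are defined on CD45RO/CD27: naive (N, CD45RO-CD27+),
early effector (eEF, CD45RO-CD27-), central memory (CM, CD45RO+CD27+)
and effector memory (EM, CD45RO+CD27-).  B-cell phenotypes on CD27/IgD:
naive (N, CD27-IgD+), early effector (eEF, CD27-IgD-), non-classical
memory (nCM, CD27+IgD+) and classical memory (CM, CD27+IgD-).
"""

from __future__ import annotations

#: Canonical column order used everywhere in the package.
PHENOTYPES: tuple[str, ...] = (
    "NCD4", "eEFCD4", "CMCD4", "EMCD4",
    "NCD8", "eEFCD8", "CMCD8", "EMCD8",
    "NCD19", "eEFCD19", "nCMCD19", "CMCD19",
)

#: Compositional lineages: the four frequencies in each sum to 100%.
LINEAGES: dict[str, tuple[str, ...]] = {
    "CD4": ("NCD4", "eEFCD4", "CMCD4", "EMCD4"),
    "CD8": ("NCD8", "eEFCD8", "CMCD8", "EMCD8"),
    "CD19": ("NCD19", "eEFCD19", "nCMCD19", "CMCD19"),
}

#: Differentiation-stage cluster families used for network node grouping:
#: naive, early effector, central/non-classical memory, effector/classical
#: memory (T and B nomenclature merged per stage).
CLUSTER_FAMILIES: dict[str, str] = {
    "NCD4": "N", "NCD8": "N", "NCD19": "N",
    "eEFCD4": "eEF", "eEFCD8": "eEF", "eEFCD19": "eEF",
    "CMCD4": "CM/nCM", "CMCD8": "CM/nCM", "nCMCD19": "CM/nCM",
    "EMCD4": "EM/CM", "EMCD8": "EM/CM", "CMCD19": "EM/CM",
}

#: Naive phenotypes contract with age; the rest are memory/effector related.
NAIVE_PHENOTYPES: tuple[str, ...] = ("NCD4", "NCD8", "NCD19")


def lineage_of(phenotype: str) -> str:
    """Return the gated lineage ('CD4', 'CD8' or 'CD19') of a phenotype."""
    for lineage, members in LINEAGES.items():
        if phenotype in members:
            return lineage
    raise KeyError(f"unknown phenotype: {phenotype!r}")
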