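"""Pathway-level regulation-consistency statistics between two treatments.

Given per-treatment differential-expression results and a pathway gene set,
the module counts, per pathway:

* ``level1_consis`` — genes significantly regulated in the chosen direction
  under *both* treatments;
* ``level2_consis`` — genes significant under exactly one treatment but
  still direction-concordant (albeit not significant) under the other;

and two Jaccard coefficients:

* ``level1_coef``  = J(sigA, sigB), agreement of the significant sets;
* ``consis_coef``  = J(sigA u L2, sigB u L2) where L2 is the level-2 gene
  set: both significant sets are augmented with the level-2 genes before
  the Jaccard.  Equivalently (level1 + level2) / |sigA u sigB|, so
  ``consis_coef >= level1_coef`` always, and it reaches 1 exactly when
  every one-sided significant gene is concordant on the other side.

Significance means |log-fold-change| above ``sig_lfc`` in the requested
direction with adjusted p below ``sig_p`` (defaults 1 and 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = ["DEResult", "ConsistencyRecord", "jaccard", "pathway_consistency",
           "consistency_table", "read_gmt", "read_de_table"]


@dataclass
class DEResult:
    """Differential-expression table: gene -> (lfc, adj_p)."""

    table: pd.DataFrame  # columns: lfc, adj_p; index: gene

    def __post_init__(self) -> None:
        if not {"lfc", "adj_p"}.issubset(self.table.columns):
            raise ValueError("DE table needs columns 'lfc' and 'adj_p'")
        if self.table.index.duplicated().any():
            dups = self.table.index[self.table.index.duplicated()].unique()
            raise ValueError(f"duplicate genes in DE table: {list(dups)[:5]}")
        bad = self.table["adj_p"].lt(0) | self.table["adj_p"].gt(1)
        if bad.any():
            raise ValueError("adjusted p-values must lie in [0, 1]")

    @property
    def genes(self) -> set[str]:
        return set(self.table.index)


@dataclass
class ConsistencyRecord:
    pathway: str
    level1_consis: int
    level2_consis: int
    level1_coef: float
    consis_coef: float
    n_genes: int
    flagged: bool = False


def jaccard(set_a, set_b) -> float:
    """|A n B| / |A u B|; defined as 0 when both sets are empty."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        warnings.warn("Jaccard of two empty sets: defined as 0")
        return 0.0
    return len(a & b) / len(union)


def pathway_consistency(pathway: str, pathway_genes, de_a: DEResult,
                        de_b: DEResult, *, direction: str = "up",
                        sig_lfc: float = 1.0, sig_p: float = 0.05) -> ConsistencyRecord:
    """Gene-level regulation agreement for one pathway between two DE runs.

    Restricted to pathway genes present in both DE tables; an empty overlap
    yields a flagged zero record.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if sig_lfc <= 0 or sig_p <= 0:
        raise ValueError("significance thresholds must be positive")
    sign = 1.0 if direction == "up" else -1.0
    genes = set(pathway_genes) & de_a.genes & de_b.genes
    if not genes:
        return ConsistencyRecord(pathway, 0, 0, 0.0, 0.0, 0, flagged=True)
    genes = sorted(genes)
    ta = de_a.table.loc[genes]
    tb = de_b.table.loc[genes]

    def classify(t):
        lfc = sign * t["lfc"]
        sig = set(t.index[(lfc > sig_lfc) & (t["adj_p"] < sig_p)])
        conc = set(t.index[lfc > 0])
        return sig, conc

    sig_a, conc_a = classify(ta)
    sig_b, conc_b = classify(tb)
    level1 = len(sig_a & sig_b)
    level2_genes = (sig_a - sig_b) & conc_b | (sig_b - sig_a) & conc_a
    level2 = len(level2_genes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        level1_coef = jaccard(sig_a, sig_b)
        consis_coef = jaccard(sig_a | level2_genes, sig_b | level2_genes)
    return ConsistencyRecord(pathway, level1, level2, level1_coef,
                             consis_coef, len(genes))


def consistency_table(pathways: dict[str, list], de_a: DEResult, de_b: DEResult,
                      **kwargs) -> pd.DataFrame:
    """Per-pathway records for a whole GMT collection, as a DataFrame."""
    records = [pathway_consistency(name, genes, de_a, de_b, **kwargs)
               for name, genes in pathways.items()]
    return pd.DataFrame([{
        "pathway": r.pathway, "level1_consis": r.level1_consis,
        "level2_consis": r.level2_consis, "level1_coef": r.level1_coef,
        "consis_coef": r.consis_coef, "n_genes": r.n_genes,
        "flagged": r.flagged} for r in records])


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file: name <tab> description <tab> gene...

    Kept in-package and dependency-free because the format is a line-per-set
    TSV and the heavy enrichment toolkits are not needed here.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs >= 3 fields")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{ln}: duplicate gene set {name!r}")
            sets[name] = [g for g in fields[2:] if g]
    if not sets:
        raise ValueError(f"{path}: empty GMT file")
    return sets


def read_de_table(path) -> DEResult:
    """Read a DE table TSV with columns gene, lfc, adj_p."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "lfc", "adj_p"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: DE table must have columns {sorted(required)}")
    return DEResult(df.set_index("gene")[["lfc", "adj_p"]])
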