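"""Differential abundance, pathway enrichment and mtDNA copy number.

Label-free proteome quantification tables (proteins x samples, linear
intensities) are compared between two groups with a volcano-style filter:
per-protein two-sided t-test on log2 intensities, significance gate at
p < alpha AND fold-change beyond the threshold in either direction.

Pathway over-representation uses the EASE-style conservative variant of the
one-sided Fisher exact test: the observed overlap k is decremented by one
before taking the hypergeometric upper tail, so single-protein overlaps can
never drive enrichment.  The classical unmodified tail is available for
comparison, and Benjamini-Hochberg correction is applied across pathways.

Pathway-level effect sizes follow the estimation-plot scheme: each protein
is z-scored across ALL samples (the overall experimental mean), per-group
per-protein means are averaged into a pathway mean z per group, and the
group difference is reported with a 95% t-interval whose unit of
replication is the member protein.

mtDNA copy number is the qPCR ratio 2^(Ct_nuclear - Ct_mito) from the
mitochondrial gene Nd1 and nuclear reference Lpl, replicate Ct values
averaged per gene first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .stats_core import bh_fdr

__all__ = [
    "AbundanceTable",
    "PathwayDef",
    "DEResult",
    "EstimationPlotStats",
    "QpcrRecords",
    "read_abundance_tsv",
    "read_sample_map",
    "read_gmt",
    "read_qpcr_csv",
    "de_filter",
    "ease_fisher",
    "enrich_pathways",
    "pathway_zscores",
    "mtdna_ratio",
    "MITO_GENE",
    "NUCLEAR_GENE",
]

MITO_GENE = "Nd1"
NUCLEAR_GENE = "Lpl"


# ---------------------------------------------------------------------------
# Containers and IO
# ---------------------------------------------------------------------------

@dataclass
class AbundanceTable:
    """Protein x sample abundance matrix with a sample->group map."""

    values: pd.DataFrame            # index: protein ids, columns: sample ids
    groups: pd.Series               # index: sample ids, values: group labels

    def __post_init__(self):
        if self.values.index.duplicated().any():
            raise ValueError("duplicate protein ids")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        unmapped = set(self.values.columns) - set(self.groups.index)
        if unmapped:
            raise ValueError(f"samples without group assignment: {sorted(unmapped)}")
        self.groups = self.groups.reindex(self.values.columns)

    def group_columns(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


@dataclass(frozen=True)
class PathwayDef:
    """Named gene set (GMT line)."""

    name: str
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"pathway {self.name!r} has no members")


def read_abundance_tsv(path, sample_map: pd.Series | Mapping[str, str]) -> AbundanceTable:
    values = pd.read_csv(path, sep="\t", index_col=0)
    return AbundanceTable(values, pd.Series(dict(sample_map) if not isinstance(sample_map, pd.Series) else sample_map))


def read_sample_map(path) -> pd.Series:
    df = pd.read_csv(path)
    return pd.Series(df["group"].to_numpy(), index=df["sample_id"])


def read_gmt(path) -> list[PathwayDef]:
    """GMT: one pathway per line, tab-separated name, description, members."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            out.append(PathwayDef(parts[0], frozenset(p for p in parts[2:] if p)))
    return out


def write_gmt(pathways: Sequence[PathwayDef], path) -> None:
    with open(path, "w") as fh:
        for pw in pathways:
            fh.write("\t".join([pw.name, "na", *sorted(pw.members)]) + "\n")


# ---------------------------------------------------------------------------
# Differential abundance
# ---------------------------------------------------------------------------

@dataclass
class DEResult:
    """Volcano-filter outcome.

    table: per tested protein — fold_change (linear treated/control ratio),
    log2_ratio, p, q (BH), direction, passed.  excluded: protein -> reason.
    """

    table: pd.DataFrame
    n_up: int
    n_down: int
    n_tested: int
    fold_threshold: float
    alpha: float
    excluded: dict[str, str] = field(default_factory=dict)

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["passed"]]


def de_filter(
    table: AbundanceTable,
    control: str,
    treated: str,
    fold_threshold: float = 1.5,
    alpha: float = 0.05,
    use_adjusted: bool = False,
) -> DEResult:
    """Two-sided per-protein t-test with a symmetric fold-change gate.

    Tests run on log2 intensities; the reported fold change is the linear
    ratio of group means of log-scale values mapped back (2**(mean log2
    difference)).  A protein passes iff p < alpha (q < alpha when
    ``use_adjusted``) and ratio >= fold_threshold or <= 1/fold_threshold.
    Proteins with zero variance in both groups are excluded with a reason.
    """
    if fold_threshold < 1:
        raise ValueError("fold_threshold must be >= 1")
    cols_a = table.group_columns(control)
    cols_b = table.group_columns(treated)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("both groups need >= 2 samples")

    vals = table.values
    if vals.empty:
        empty = pd.DataFrame(
            columns=["fold_change", "log2_ratio", "p", "q", "direction", "passed"]
        )
        return DEResult(empty, 0, 0, 0, fold_threshold, alpha)
    if np.any(vals.to_numpy() <= 0):
        raise ValueError("abundances must be positive (linear scale)")
    log2 = np.log2(vals)
    a = log2[cols_a].to_numpy(dtype=float)
    b = log2[cols_b].to_numpy(dtype=float)

    var_a = a.var(axis=1)
    var_b = b.var(axis=1)
    degenerate = (var_a == 0) & (var_b == 0)
    excluded = {
        str(pid): "zero variance in both groups"
        for pid in vals.index[degenerate]
    }

    keep = ~degenerate
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(b[keep], a[keep], axis=1)
    log2_ratio = b.mean(axis=1) - a.mean(axis=1)
    out = pd.DataFrame(index=vals.index[keep])
    out["log2_ratio"] = log2_ratio[keep]
    out["fold_change"] = 2.0 ** out["log2_ratio"]
    out["p"] = res.pvalue
    out["q"] = bh_fdr(res.pvalue) if len(out) else []
    out["direction"] = np.where(out["log2_ratio"] > 0, "up", "down")
    gate_p = out["q"] if use_adjusted else out["p"]
    fold_ok = (out["fold_change"] >= fold_threshold) | (out["fold_change"] <= 1 / fold_threshold)
    out["passed"] = (gate_p < alpha) & fold_ok
    n_up = int(((out["direction"] == "up") & out["passed"]).sum())
    n_down = int(((out["direction"] == "down") & out["passed"]).sum())
    return DEResult(out, n_up, n_down, len(out), fold_threshold, alpha, excluded)


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def ease_fisher(
    overlap: int,
    de_size: int,
    pathway_size: int,
    universe: int,
    variant: Literal["ease", "classic"] = "ease",
) -> float:
    """One-sided over-representation p for a DE-list/pathway overlap.

    ``classic`` is the hypergeometric upper tail P(X >= k); ``ease``
    substitutes max(k-1, 0) for k before taking the tail, the conservative
    "subtract one hit" penalization.  X ~ Hypergeom(N=universe,
    K=pathway_size, n=de_size).
    """
    k, n, K, N = overlap, de_size, pathway_size, universe
    if not (0 <= k <= min(n, K)):
        raise ValueError("overlap exceeds list or pathway size")
    if N < max(n, K) or min(n, K, N) < 0:
        raise ValueError("inconsistent 2x2 margins")
    if variant == "ease":
        k = max(k - 1, 0)
    elif variant != "classic":
        raise ValueError("variant must be 'ease' or 'classic'")
    # sf(k-1) = P(X >= k)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_pathways(
    de_proteins: Sequence[str],
    pathways: Sequence[PathwayDef],
    universe: Sequence[str],
    variant: Literal["ease", "classic"] = "ease",
) -> pd.DataFrame:
    """EASE-style enrichment of every pathway against a DE list, BH-corrected.

    Pathway membership is intersected with the measured universe; the
    intersection size is reported so shrunken pathways are visible.
    """
    uni = set(universe)
    de = set(de_proteins) & uni
    rows = []
    for pw in pathways:
        members = pw.members & uni
        k = len(de & members)
        p = ease_fisher(k, len(de), len(members), len(uni), variant=variant) if members else 1.0
        rows.append(
            {"pathway": pw.name, "overlap": k, "pathway_in_universe": len(members),
             "de_size": len(de), "universe": len(uni), "p": p}
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Estimation-plot z-scores
# ---------------------------------------------------------------------------

@dataclass
class EstimationPlotStats:
    """Pathway-level z-score effect size.

    protein_z: per member protein, mean z per group; pathway means, the
    group mean difference and its 95% CI over member proteins.
    """

    pathway: str
    protein_z: pd.DataFrame          # index protein, columns = group labels
    group_means: dict[str, float]
    mean_difference: float
    ci_low: float
    ci_high: float
    singleton: bool = False


def pathway_zscores(
    table: AbundanceTable,
    pathway: PathwayDef,
    control: str,
    treated: str,
) -> EstimationPlotStats:
    """Estimation-plot statistics for one pathway.

    Each member protein is z-scored across ALL samples (population SD), so
    over/under-representation is relative to the overall experimental
    mean.  The difference CI is the 95% t-interval with member proteins as
    the unit of replication; singleton pathways get a NaN-width CI and a
    flag.
    """
    members = sorted(pathway.members & set(table.values.index))
    if not members:
        raise ValueError(f"pathway {pathway.name!r} shares no proteins with the table")
    sub = table.values.loc[members]
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=0)
    if np.any(sd.to_numpy() == 0):
        raise ValueError("zero-variance protein cannot be z-scored")
    z = sub.sub(mu, axis=0).div(sd, axis=0)

    cols = {g: table.group_columns(g) for g in (control, treated)}
    protein_z = pd.DataFrame(
        {g: z[c].mean(axis=1) for g, c in cols.items()}
    )
    group_means = {g: float(protein_z[g].mean()) for g in protein_z.columns}
    per_protein_diff = (protein_z[treated] - protein_z[control]).to_numpy()
    diff = float(per_protein_diff.mean())
    if len(members) < 2:
        lo = hi = float("nan")
        singleton = True
    else:
        sem = stats.sem(per_protein_diff)
        if sem == 0:  # all member proteins shifted identically
            lo = hi = diff
        else:
            lo, hi = stats.t.interval(0.95, len(members) - 1, loc=diff, scale=sem)
        singleton = False
    return EstimationPlotStats(
        pathway=pathway.name,
        protein_z=protein_z,
        group_means=group_means,
        mean_difference=diff,
        ci_low=float(lo),
        ci_high=float(hi),
        singleton=singleton,
    )


# ---------------------------------------------------------------------------
# mtDNA copy number
# ---------------------------------------------------------------------------

@dataclass
class QpcrRecords:
    """qPCR Ct table: animal_id, group, gene, replicate, ct."""

    data: pd.DataFrame

    def __post_init__(self):
        need = {"animal_id", "group", "gene", "replicate", "ct"}
        missing = need - set(self.data.columns)
        if missing:
            raise ValueError(f"qPCR table missing column(s): {sorted(missing)}")
        ct = self.data["ct"].to_numpy(dtype=float)
        if np.any((ct <= 0) | (ct >= 45)):
            raise ValueError("Ct values must lie in (0, 45)")


def read_qpcr_csv(path) -> QpcrRecords:
    return QpcrRecords(pd.read_csv(path))


def mtdna_ratio(
    records: QpcrRecords,
    mito_gene: str = MITO_GENE,
    nuclear_gene: str = NUCLEAR_GENE,
) -> pd.DataFrame:
    """Relative mtDNA/nDNA ratio per animal: 2^(Ct_nuclear - Ct_mito).

    Replicate Cts are averaged per gene first.  Ratios are relative (no
    diploid correction); only group contrasts are meaningful.
    """
    df = records.data
    mean_ct = df.groupby(["animal_id", "group", "gene"])["ct"].mean().unstack("gene")
    for gene in (mito_gene, nuclear_gene):
        bad = mean_ct.index[mean_ct[gene].isna()] if gene in mean_ct else mean_ct.index
        if gene not in mean_ct.columns or len(bad):
            animals = [a for a, _ in bad] if gene in mean_ct.columns else "all"
            raise ValueError(f"gene {gene!r} missing for animal(s): {animals}")
    out = mean_ct.reset_index()
    out["ratio"] = 2.0 ** (out[nuclear_gene] - out[mito_gene])
    return out[["animal_id", "group", mito_gene, nuclear_gene, "ratio"]]
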