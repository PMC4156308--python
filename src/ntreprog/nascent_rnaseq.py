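"""Gene-state classification from donor vs NT nascent transcriptomes.

A gene is called expressed in a condition only if its CPM exceeds 1 in every
replicate of that condition.  Differential transcription between pooled donor
and NT counts is assessed with a two-sided exact conditional binomial test
(given the total count, the donor share is binomial with success probability
set by the library-size ratio), BH-corrected across genes.  Genes are then
partitioned into reprogrammed / maintained / downregulated / silent, matching
the published three-way classification of the expressed universe.

Also provides RPKM-based ortholog comparison, sample clustering on Spearman
distances, and hypergeometric gene-set enrichment.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .io_formats import CountMatrix, GeneModel

LABELS = ("reprogrammed", "maintained", "downregulated", "silent")


@dataclass
class DEResult:
    """Per-gene differential-transcription statistics.

    ``log2fc`` is log2(group_b CPM / group_a CPM) with a 0.5-CPM pseudocount
    on both sides, so a donor-vs-NT call gives reprogrammed genes a positive
    sign (the published legend writes the ratio the other way round).
    """

    table: pd.DataFrame  # columns: count_a, count_b, log2fc, p_value, fdr
    group_a: str
    group_b: str

    @property
    def log2fc(self) -> pd.Series:
        return self.table["log2fc"]

    @property
    def p_value(self) -> pd.Series:
        return self.table["p_value"]

    @property
    def fdr(self) -> pd.Series:
        return self.table["fdr"]


@dataclass
class GeneClassification:
    """Per-gene label plus the expression calls that produced it."""

    table: pd.DataFrame  # columns: label, expressed_donor, expressed_NT

    @property
    def label(self) -> pd.Series:
        return self.table["label"]

    def counts(self) -> dict[str, int]:
        vc = self.label.value_counts()
        return {c: int(vc.get(c, 0)) for c in LABELS}


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def compute_cpm(cm: CountMatrix) -> pd.DataFrame:
    """Counts per million: counts / library_size * 1e6 per sample."""
    if (cm.library_size <= 0).any():
        raise ValueError("library sizes must be positive")
    return cm.counts / cm.library_size * 1e6


def compute_rpkm(cm: CountMatrix, gene_lengths: Mapping[str, int] | pd.Series) -> pd.DataFrame:
    """Reads per kilobase per million: CPM scaled by exonic length in kb."""
    lengths = pd.Series(gene_lengths)
    missing = cm.gene_ids.difference(lengths.index)
    if len(missing):
        raise ValueError(f"missing gene lengths for {list(missing)[:5]}...")
    lengths = lengths.loc[cm.gene_ids].astype(float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    return compute_cpm(cm).div(lengths / 1e3, axis=0)


def gene_lengths_from_models(genes: Sequence[GeneModel]) -> pd.Series:
    return pd.Series({g.gene_id: g.exonic_length for g in genes})


# ---------------------------------------------------------------------------
# detection and differential transcription
# ---------------------------------------------------------------------------

def detect_expressed(
    cpm: pd.DataFrame, cm: CountMatrix, condition: str, threshold: float = 1.0
) -> pd.Series:
    """Expressed iff CPM strictly exceeds the threshold in every replicate."""
    samples = cm.samples_of(condition)
    if len(samples) < 2:
        raise ValueError(f"need >= 2 replicates in condition {condition!r}")
    return (cpm[samples] > threshold).all(axis=1)


def de_exact_test(cm: CountMatrix, group_a: str, group_b: str) -> DEResult:
    """Two-sided exact conditional binomial test on pooled replicate counts.

    Per gene, with A and B the summed counts in the two conditions and
    T = A + B, A ~ Binomial(T, L_a / (L_a + L_b)) under the null of equal
    concentration; the two-sided p sums outcome probabilities no larger than
    the observed one.  Genes with T = 0 get p = 1 and are excluded from the
    BH correction.
    """
    sa, sb = cm.samples_of(group_a), cm.samples_of(group_b)
    if set(sa) & set(sb):
        raise ValueError("conditions share samples")
    a = cm.counts[sa].sum(axis=1)
    b = cm.counts[sb].sum(axis=1)
    la = float(cm.library_size[sa].sum())
    lb = float(cm.library_size[sb].sum())
    pi0 = la / (la + lb)
    t = a + b

    p = np.ones(len(a))
    nz = t.to_numpy() > 0
    av, tv = a.to_numpy(), t.to_numpy()
    for i in np.nonzero(nz)[0]:
        p[i] = stats.binomtest(int(av[i]), int(tv[i]), pi0).pvalue
    fdr = np.ones(len(a))
    if nz.any():
        fdr[nz] = multipletests(p[nz], method="fdr_bh")[1]

    cpm_a = av / la * 1e6
    cpm_b = b.to_numpy() / lb * 1e6
    log2fc = np.log2((cpm_b + 0.5) / (cpm_a + 0.5))
    table = pd.DataFrame(
        {"count_a": av, "count_b": b.to_numpy(), "log2fc": log2fc, "p_value": p, "fdr": fdr},
        index=cm.gene_ids,
    )
    return DEResult(table, group_a, group_b)


def estimate_common_dispersion(cm: CountMatrix) -> float:
    """Method-of-moments common NB dispersion across genes and conditions.

    Counts are first rescaled to a common depth; per gene and condition the
    excess of the sample variance over the mean, relative to the squared mean,
    estimates the dispersion; the median over informative genes (mean count
    > 5) is returned, floored at zero.
    """
    phis = []
    mean_lib = float(cm.library_size.mean())
    for cond in cm.condition.unique():
        samples = cm.samples_of(cond)
        if len(samples) < 2:
            continue
        scaled = cm.counts[samples] * (mean_lib / cm.library_size[samples])
        m = scaled.mean(axis=1).to_numpy()
        v = scaled.var(axis=1, ddof=1).to_numpy()
        ok = m > 5
        if ok.any():
            phis.append((v[ok] - m[ok]) / m[ok] ** 2)
    if not phis:
        return 0.0
    return float(max(0.0, np.median(np.concatenate(phis))))


def de_nb_quasi_test(cm: CountMatrix, group_a: str, group_b: str) -> DEResult:
    """Dispersion-inflated alternative to the exact test (quasi-binomial z test).

    A common NB dispersion is estimated by the method of moments and the
    conditional binomial variance of the pooled donor count is inflated by
    1 + dispersion * (mean per-sample count); the two-sided p comes from the
    normal approximation.  Use when replicate noise is clearly super-Poisson.
    """
    sa, sb = cm.samples_of(group_a), cm.samples_of(group_b)
    if set(sa) & set(sb):
        raise ValueError("conditions share samples")
    phi = estimate_common_dispersion(cm)
    a = cm.counts[sa].sum(axis=1).to_numpy()
    b = cm.counts[sb].sum(axis=1).to_numpy()
    la = float(cm.library_size[sa].sum())
    lb = float(cm.library_size[sb].sum())
    pi0 = la / (la + lb)
    t = a + b
    n_samples = len(sa) + len(sb)
    with np.errstate(divide="ignore", invalid="ignore"):
        inflation = 1.0 + phi * t / n_samples
        z = (a - t * pi0) / np.sqrt(t * pi0 * (1 - pi0) * inflation)
    p = np.where(t > 0, 2.0 * stats.norm.sf(np.abs(z)), 1.0)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    fdr = np.ones(len(p))
    nz = t > 0
    if nz.any():
        fdr[nz] = multipletests(p[nz], method="fdr_bh")[1]
    log2fc = np.log2((b / lb * 1e6 + 0.5) / (a / la * 1e6 + 0.5))
    table = pd.DataFrame(
        {"count_a": a, "count_b": b, "log2fc": log2fc, "p_value": p, "fdr": fdr},
        index=cm.gene_ids,
    )
    return DEResult(table, group_a, group_b)


def classify_genes(
    expressed_donor: pd.Series,
    expressed_nt: pd.Series,
    de: DEResult,
    alpha: float = 0.05,
) -> GeneClassification:
    """Partition genes into reprogrammed / maintained / downregulated / silent.

    Reprogrammed: expressed after NT and either absent in the donor or
    significantly up.  Downregulated: the mirror image.  Maintained: expressed
    in both without a significant change.  Silent: expressed in neither.
    """
    if not expressed_donor.index.equals(expressed_nt.index) or not expressed_donor.index.equals(
        de.table.index
    ):
        raise ValueError("gene universes of the inputs differ")
    sig = de.fdr < alpha
    up = sig & (de.log2fc > 0)
    down = sig & (de.log2fc < 0)
    label = pd.Series("maintained", index=expressed_donor.index)
    label[expressed_nt & (~expressed_donor | up)] = "reprogrammed"
    label[expressed_donor & (~expressed_nt | down) & ~(expressed_nt & (~expressed_donor | up))] = (
        "downregulated"
    )
    label[~expressed_donor & ~expressed_nt] = "silent"
    table = pd.DataFrame(
        {"label": label, "expressed_donor": expressed_donor, "expressed_NT": expressed_nt}
    )
    return GeneClassification(table)


def class_percentages_from_counts(
    downregulated: int, maintained: int, reprogrammed: int
) -> pd.DataFrame:
    """Class shares of the expressed universe (union of the three classes).

    Also reports the reprogrammed share of NT-expressed genes
    (denominator = maintained + reprogrammed).
    """
    universe = downregulated + maintained + reprogrammed
    if universe == 0:
        raise ValueError("empty expressed universe")
    nt_expressed = maintained + reprogrammed
    rows = {
        "downregulated": (downregulated, 100.0 * downregulated / universe),
        "maintained": (maintained, 100.0 * maintained / universe),
        "reprogrammed": (reprogrammed, 100.0 * reprogrammed / universe),
    }
    out = pd.DataFrame(rows, index=["count", "percent_of_universe"]).T
    out["count"] = out["count"].astype(int)
    out.attrs["universe"] = universe
    out.attrs["nt_expressed"] = nt_expressed
    out.attrs["reprogrammed_percent_of_nt_expressed"] = (
        100.0 * reprogrammed / nt_expressed if nt_expressed else np.nan
    )
    return out


def class_percentages(cls: GeneClassification) -> pd.DataFrame:
    c = cls.counts()
    return class_percentages_from_counts(c["downregulated"], c["maintained"], c["reprogrammed"])


# ---------------------------------------------------------------------------
# ortholog comparison
# ---------------------------------------------------------------------------

def ortholog_compare(
    nt_rpkm: pd.Series,
    oocyte_rpkm: pd.Series,
    ortholog_map: pd.DataFrame,
    split: str = "tercile",
    threshold: float | None = None,
) -> dict:
    """Compare NT expression of host orthologs of high- vs low-expressed oocyte genes.

    Oocyte genes are split into high and low sets (top vs bottom tercile of
    oocyte RPKM by default, or a fixed threshold); a Welch two-sample t test is
    run on log2(RPKM + 1) of the mapped host genes.  Returns box-plot style
    summaries per group plus the statistic and p value.
    """
    pairs = ortholog_map.dropna()
    pairs = pairs[
        pairs["host_gene_id"].isin(nt_rpkm.index) & pairs["oocyte_gene_id"].isin(oocyte_rpkm.index)
    ]
    if pairs["host_gene_id"].duplicated().any():
        raise ValueError("ortholog map is not injective on analyzed host genes")
    ooc = oocyte_rpkm.loc[pairs["oocyte_gene_id"]].to_numpy()
    host = np.log2(nt_rpkm.loc[pairs["host_gene_id"]].to_numpy() + 1.0)

    if split == "tercile":
        lo_cut, hi_cut = np.quantile(ooc, [1 / 3, 2 / 3])
        low_mask = ooc <= lo_cut
        high_mask = ooc > hi_cut
    elif split == "threshold":
        if threshold is None:
            raise ValueError("threshold split requires a threshold")
        low_mask = ooc <= threshold
        high_mask = ooc > threshold
    else:
        raise ValueError(f"unknown split {split!r}")

    low, high = host[low_mask], host[high_mask]
    if len(low) < 10 or len(high) < 10:
        raise ValueError("need at least 10 genes per group")
    t, p = stats.ttest_ind(high, low, equal_var=False)

    def summary(x: np.ndarray) -> dict:
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        return {"n": int(len(x)), "median": float(med), "q1": float(q1), "q3": float(q3)}

    return {"high": summary(high), "low": summary(low), "t": float(t), "p": float(p), "split": split}


# ---------------------------------------------------------------------------
# sample clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    labels: list[str]
    linkage: np.ndarray
    newick: str


def hierarchical_cluster(expr: pd.DataFrame) -> ClusterResult:
    """Average-linkage clustering of samples on 1 - Spearman correlation.

    Spearman is robust to the heavy-tailed RPKM scale.  A constant sample
    column has no defined rank correlation and is rejected by name.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    for s in expr.columns:
        if expr[s].nunique() <= 1:
            raise ValueError(f"sample {s!r} is constant; correlation undefined")
    rho = stats.spearmanr(expr.to_numpy()).statistic
    rho = np.atleast_2d(rho)
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    z = sch.linkage(squareform(dist, checks=False), method="average")
    labels = list(expr.columns)
    tree = sch.to_tree(z)

    def newick(node, parent_height: float) -> str:
        length = parent_height - (node.dist if not node.is_leaf() else 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = newick(node.left, node.dist)
        right = newick(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return ClusterResult(labels, z, newick(tree, tree.dist) + ";")


# ---------------------------------------------------------------------------
# gene-set enrichment
# ---------------------------------------------------------------------------

def geneset_enrichment(
    hits: set[str], universe: set[str], collections: Mapping[str, set[str]]
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of each named set among the hits.

    Each collection set is intersected with the universe before testing; sets
    that become empty are flagged and assigned p = 1.  BH correction across
    collections.
    """
    if not universe:
        raise ValueError("empty gene universe")
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    m, n_hits = len(universe), len(hits)
    rows = []
    for name, members in collections.items():
        inset = members & universe
        k = len(inset & hits)
        if not inset:
            rows.append((name, 0, 0, np.nan, 1.0, True))
            continue
        p = float(stats.hypergeom.sf(k - 1, m, len(inset), n_hits))
        expected = n_hits * len(inset) / m
        rows.append((name, len(inset), k, expected, p, False))
    out = pd.DataFrame(
        rows, columns=["set", "set_size", "overlap", "expected", "p_value", "empty_after_intersection"]
    ).set_index("set")
    out["fdr"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1] if len(out) else []
    return out
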