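import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ntreprog import nascent_rnaseq as nr
from ntreprog import synthetic_data as sd
from ntreprog.io_formats import CountMatrix


def _cm(counts: dict, conditions: dict, libsize: dict | None = None, genes=None) -> CountMatrix:
    df = pd.DataFrame(counts, index=genes or [f"g{i}" for i in range(len(next(iter(counts.values()))))])
    reps: dict[str, int] = {}
    seen: dict[str, int] = {}
    for s, c in conditions.items():
        seen[c] = seen.get(c, 0) + 1
        reps[s] = seen[c]
    return CountMatrix.from_frame(df, conditions, reps, libsize)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def test_cpm_basic_value_and_column_identity():
    cm = _cm({"s1": [10, 0], "s2": [5, 5]}, {"s1": "donor", "s2": "NT"},
             {"s1": 10**6, "s2": 10**6})
    cpm = nr.compute_cpm(cm)
    assert cpm.loc["g0", "s1"] == 10.0
    # with default (column-sum) library sizes, CPM columns sum to 1e6 exactly
    cm2 = _cm({"s1": [10, 30], "s2": [5, 5]}, {"s1": "donor", "s2": "NT"})
    assert np.allclose(nr.compute_cpm(cm2).sum(axis=0), 1e6)


def test_rpkm_equals_cpm_scaled_by_length():
    cm = _cm({"s1": [100, 7], "s2": [50, 3]}, {"s1": "donor", "s2": "NT"},
             {"s1": 10**6, "s2": 10**6})
    lengths = pd.Series({"g0": 1000, "g1": 2000})
    rpkm = nr.compute_rpkm(cm, lengths)
    cpm = nr.compute_cpm(cm)
    assert rpkm.loc["g0", "s1"] == 100.0
    assert np.allclose(rpkm, cpm.mul(1e3 / lengths, axis=0))
    # doubling length halves RPKM
    half = nr.compute_rpkm(cm, lengths * 2)
    assert np.allclose(half, rpkm / 2)
    with pytest.raises(ValueError):
        nr.compute_rpkm(cm, pd.Series({"g0": 1000}))


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "cpms,expected",
    [
        ((1.2, 1.5, 0.8), False),  # one replicate below threshold
        ((1.01, 1.01, 1.01), True),
        ((1.0, 2.0, 3.0), False),  # strict inequality at the boundary
    ],
)
def test_detect_expressed_requires_all_replicates_above_threshold(cpms, expected):
    lib = 10**6
    counts = {f"d{i}": [int(c * lib / 1e6)] for i, c in enumerate(cpms)}
    # build CPM frame directly to avoid integer rounding of the boundary cases
    cm = _cm({k: [1] for k in counts}, {k: "donor" for k in counts},
             {k: lib for k in counts}, genes=["g0"])
    cpm = pd.DataFrame({k: [c] for k, c in zip(counts, cpms)}, index=["g0"])
    assert nr.detect_expressed(cpm, cm, "donor").loc["g0"] == expected


def test_detect_expressed_unknown_condition_errors(small_counts):
    cpm = nr.compute_cpm(small_counts)
    with pytest.raises(ValueError):
        nr.detect_expressed(cpm, small_counts, "oocyte")


# ---------------------------------------------------------------------------
# exact DE test
# ---------------------------------------------------------------------------

def test_exact_test_matches_binomial_tail_enumeration():
    """A=0, B=20 at equal library sizes: two-sided p = 2 * 2^-20."""
    cm = _cm(
        {"d1": [0], "d2": [0], "n1": [10], "n2": [10]},
        {"d1": "donor", "d2": "donor", "n1": "NT", "n2": "NT"},
        {s: 10**6 for s in ("d1", "d2", "n1", "n2")},
        genes=["g0"],
    )
    de = nr.de_exact_test(cm, "donor", "NT")
    assert de.p_value.loc["g0"] == pytest.approx(2 * 0.5**20, rel=1e-9)
    assert de.log2fc.loc["g0"] > 0


def test_exact_test_symmetric_outcome_gives_p_one():
    cm = _cm(
        {"d1": [15], "n1": [15]}, {"d1": "donor", "n1": "NT"},
        {"d1": 10**6, "n1": 10**6}, genes=["g0"],
    )
    # pooled counts equal at equal depth: modal symmetric outcome
    cm.replicate["d1"] = 1
    de = nr.de_exact_test(cm, "donor", "NT")
    assert de.p_value.loc["g0"] == pytest.approx(1.0)
    assert de.table.loc["g0", "log2fc"] == pytest.approx(0.0)


def test_exact_test_zero_total_gets_p_one():
    cm = _cm(
        {"d1": [0, 5], "n1": [0, 9]}, {"d1": "donor", "n1": "NT"},
        {"d1": 10**6, "n1": 10**6},
    )
    de = nr.de_exact_test(cm, "donor", "NT")
    assert de.p_value.loc["g0"] == 1.0
    assert de.fdr.loc["g0"] == 1.0


@given(
    a=st.integers(min_value=0, max_value=200),
    b=st.integers(min_value=0, max_value=200),
    la=st.integers(min_value=10**5, max_value=10**6),
    lb=st.integers(min_value=10**5, max_value=10**6),
)
@settings(max_examples=25, deadline=None)
def test_exact_test_is_symmetric_under_group_swap(a, b, la, lb):
    cm = _cm({"d1": [a], "n1": [b]}, {"d1": "donor", "n1": "NT"},
             {"d1": la, "n1": lb}, genes=["g0"])
    fwd = nr.de_exact_test(cm, "donor", "NT")
    rev = nr.de_exact_test(cm, "NT", "donor")
    assert fwd.p_value.loc["g0"] == pytest.approx(rev.p_value.loc["g0"], rel=1e-12)
    assert fwd.log2fc.loc["g0"] == pytest.approx(-rev.log2fc.loc["g0"], rel=1e-12)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _classification(ed, en, lfc, fdr, alpha=0.05):
    genes = [f"g{i}" for i in range(len(ed))]
    de = nr.DEResult(
        pd.DataFrame(
            {"count_a": 1, "count_b": 1, "log2fc": lfc, "p_value": fdr, "fdr": fdr},
            index=genes,
        ),
        "donor",
        "NT",
    )
    return nr.classify_genes(
        pd.Series(ed, index=genes), pd.Series(en, index=genes), de, alpha
    )


@pytest.mark.parametrize(
    "ed,en,lfc,fdr,expected",
    [
        (True, False, -2.0, 0.001, "downregulated"),  # donor-only, significant down
        (True, True, 0.5, 0.5, "maintained"),  # both expressed, not significant
        (False, True, 3.0, 0.001, "reprogrammed"),
        (True, True, 3.0, 0.001, "reprogrammed"),  # both expressed but strongly up
        (True, True, -3.0, 0.001, "downregulated"),
        (False, False, 0.0, 1.0, "silent"),
    ],
)
def test_classification_rules(ed, en, lfc, fdr, expected):
    cls = _classification([ed], [en], [lfc], [fdr])
    assert cls.label.iloc[0] == expected


@given(st.lists(st.tuples(st.booleans(), st.booleans(),
                          st.floats(-5, 5, allow_nan=False),
                          st.floats(0.001, 1.0)), min_size=1, max_size=40))
@settings(max_examples=50, deadline=None)
def test_classification_is_a_partition(rows):
    ed, en, lfc, fdr = zip(*rows)
    cls = _classification(list(ed), list(en), list(lfc), list(fdr))
    assert sum(cls.counts().values()) == len(rows)  # labels partition the universe
    # structural invariants of the labels
    t = cls.table
    assert t.loc[t.label == "reprogrammed", "expressed_NT"].all()
    assert t.loc[t.label == "downregulated", "expressed_donor"].all()
    assert (t.loc[t.label == "maintained", ["expressed_donor", "expressed_NT"]].all(axis=1)).all()


def test_class_percentages_single_class_edge():
    pct = nr.class_percentages_from_counts(1, 0, 0)
    assert pct.loc["downregulated", "percent_of_universe"] == 100.0
    with pytest.raises(ValueError):
        nr.class_percentages_from_counts(0, 0, 0)


# ---------------------------------------------------------------------------
# ortholog comparison
# ---------------------------------------------------------------------------

def _ortho_inputs(rng, n=300, shift=0.0):
    host_ids = [f"m{i}" for i in range(n)]
    ooc_ids = [f"x{i}" for i in range(n)]
    ooc = pd.Series(np.exp(rng.normal(2, 1.5, n)), index=ooc_ids)
    order = np.argsort(ooc.to_numpy())
    base = rng.normal(4, 1, n)
    hi = order[-(n // 3):]
    base[hi] += shift
    host = pd.Series(2.0 ** base, index=host_ids)
    mapping = pd.DataFrame({"host_gene_id": host_ids, "oocyte_gene_id": ooc_ids})
    return host, ooc, mapping


def test_ortholog_compare_detects_strong_shift(rng):
    host, ooc, mapping = _ortho_inputs(rng, n=600, shift=2.0)
    res = nr.ortholog_compare(host, ooc, mapping)
    assert res["p"] < 1e-16
    assert res["high"]["median"] > res["low"]["median"]


def test_ortholog_compare_null_gives_moderate_statistic(rng):
    host, ooc, mapping = _ortho_inputs(rng, n=600, shift=0.0)
    res = nr.ortholog_compare(host, ooc, mapping)
    assert abs(res["t"]) < 4


def test_ortholog_compare_rejects_tiny_groups():
    host = pd.Series([1.0], index=["m0"])
    ooc = pd.Series([1.0], index=["x0"])
    mapping = pd.DataFrame({"host_gene_id": ["m0"], "oocyte_gene_id": ["x0"]})
    with pytest.raises(ValueError):
        nr.ortholog_compare(host, ooc, mapping)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def test_cluster_duplicated_sample_merges_at_zero_height(rng):
    x = rng.normal(size=50)
    df = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=50)})
    res = nr.hierarchical_cluster(df)
    assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
    assert sorted(res.linkage[0, :2]) == [0, 1]


def test_cluster_anticorrelated_sample_joins_last(rng):
    x = rng.normal(size=60)
    df = pd.DataFrame({"a": x, "b": x + rng.normal(0, 0.01, 60), "c": -x})
    res = nr.hierarchical_cluster(df)
    # the identical pair merges first, the anti-correlated sample joins at ~2
    assert res.linkage[0, 2] < 0.1
    assert res.linkage[1, 2] > 1.5
    assert res.newick.count("(") == 2


def test_cluster_nt_samples_form_clade_with_oocyte_profile(rng):
    """NT replicates sharing the oocyte-ortholog profile cluster away from donors."""
    oocyte = rng.normal(5, 2, 400)
    donor = rng.normal(5, 2, 400)
    df = pd.DataFrame(
        {
            "donor_1": donor + rng.normal(0, 0.3, 400),
            "donor_2": donor + rng.normal(0, 0.3, 400),
            "NT_1": oocyte + rng.normal(0, 0.3, 400),
            "NT_2": oocyte + rng.normal(0, 0.3, 400),
            "oocyte_orthologs": oocyte + rng.normal(0, 0.3, 400),
        }
    )
    res = nr.hierarchical_cluster(df)
    import re

    # find the smallest clade containing all NT/oocyte labels: parse newick clades
    nwk = res.newick
    clades = []

    def collect(s):
        stack = []
        for i, ch in enumerate(s):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                clades.append(s[stack.pop(): i + 1])

    collect(nwk)
    target = {"NT_1", "NT_2", "oocyte_orthologs"}
    best = None
    for c in clades:
        leaves = set(re.findall(r"[\w]+(?=:)", c)) & set(res.labels)
        if target <= leaves and (best is None or len(leaves) < len(best)):
            best = leaves
    assert best == target  # the NT + oocyte clade excludes the donors


def test_cluster_rejects_constant_sample():
    df = pd.DataFrame({"a": [1, 2, 3], "b": [2, 2, 2], "c": [3, 1, 2]})
    with pytest.raises(ValueError, match="b"):
        nr.hierarchical_cluster(df)


# ---------------------------------------------------------------------------
# gene-set enrichment
# ---------------------------------------------------------------------------

def test_enrichment_exact_probability_full_overlap():
    """5 hits, one set of exactly those 5 genes in a 20-gene universe: p = 1/C(20,5)."""
    from math import comb

    universe = {f"g{i}" for i in range(20)}
    hits = {f"g{i}" for i in range(5)}
    res = nr.geneset_enrichment(hits, universe, {"S": set(hits)})
    assert res.loc["S", "p_value"] == pytest.approx(1 / comb(20, 5), rel=1e-9)


def test_enrichment_overlap_at_expectation_is_not_significant(rng):
    universe = {f"g{i}" for i in range(100)}
    hits = {f"g{i}" for i in range(50)}  # half the universe
    members = {f"g{i}" for i in range(45, 55)}  # overlap 5 = expectation
    res = nr.geneset_enrichment(hits, universe, {"S": members})
    assert res.loc["S", "p_value"] >= 0.5


def test_enrichment_flags_empty_set_and_checks_subset():
    universe = {"a", "b"}
    res = nr.geneset_enrichment({"a"}, universe, {"S": {"z"}})
    assert res.loc["S", "empty_after_intersection"]
    assert res.loc["S", "p_value"] == 1.0
    with pytest.raises(ValueError):
        nr.geneset_enrichment({"q"}, universe, {})


# ---------------------------------------------------------------------------
# quasi-NB alternative
# ---------------------------------------------------------------------------

def test_quasi_test_controls_fdr_under_strong_overdispersion():
    d = sd.SimDesign(
        n_genes=1000,
        class_fractions={"maintained": 1.0, "reprogrammed": 0, "downregulated": 0, "silent": 0},
        dispersion=0.1,
        seed=2,
    )
    cm, _ = sd.simulate_nascent_counts(d)
    de = nr.de_nb_quasi_test(cm, "donor", "NT")
    assert (de.fdr < 0.05).mean() <= 0.05
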