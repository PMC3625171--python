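"""Reporter-ratio statistics: weighting, normalization, Grubbs, CI calls."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coccoproteome.itraq import (
    PSM,
    Design,
    PeptideRatio,
    calls_from_replicate_ratios,
    classify_regulation,
    grubbs_critical_value,
    median_normalize,
    peptide_ratio,
    protein_replicate_ratio,
    quantify_experiment,
    remove_outliers,
    replicate_geomean_ci,
)
from coccoproteome.reference_ratios import reference_ratio_table


def _psm(**intens):
    return PSM("s1", "PEPTIDEK", "P1", {int(k[1:]): v for k, v in intens.items()})


def test_peptide_ratio_basic():
    pr = peptide_ratio(_psm(i114=500.0, i113=500.0), 114, 113)
    assert pr.ratio == 1.0 and pr.weight == 1000.0
    assert peptide_ratio(_psm(i114=800.0, i113=400.0), 114, 113).ratio == 2.0


def test_peptide_ratio_zero_channel_excluded():
    assert peptide_ratio(_psm(i114=0.0, i113=400.0), 114, 113) is None


def _ratios(vals, weight=1.0):
    return [PeptideRatio(ratio=v, weight=weight) for v in vals]


@pytest.mark.parametrize(
    "vals,expected",
    [([2, 2, 2], [1, 1, 1]), ([1, 2, 4], [0.5, 1, 2])],
)
def test_median_normalize(vals, expected):
    out = median_normalize(_ratios(vals))
    assert [r.ratio for r in out] == pytest.approx(expected)


@given(st.lists(st.floats(min_value=0.01, max_value=100.0), min_size=1, max_size=30))
@settings(max_examples=50, deadline=None)
def test_median_normalize_median_is_one(vals):
    out = median_normalize(_ratios(vals))
    assert float(np.median([r.ratio for r in out])) == pytest.approx(1.0, rel=1e-9)


def test_grubbs_critical_values_match_published_table():
    # two-sided alpha = 0.05 reference values
    published = {3: 1.1543, 4: 1.4812, 5: 1.7150, 6: 1.8871, 10: 2.2900}
    for n, g in published.items():
        assert grubbs_critical_value(n, 0.05) == pytest.approx(g, abs=2e-3)


def test_remove_outliers_detects_gross_outlier():
    # G = 1.495 > 1.481 (n = 4 critical value): 2.0 removed
    assert remove_outliers([0.0, 0.1, -0.1, 2.0], alpha=0.05) == [0.0, 0.1, -0.1]


def test_remove_outliers_keeps_clean_samples():
    assert remove_outliers([0.0, 0.1, -0.1], alpha=0.05) == [0.0, 0.1, -0.1]
    assert remove_outliers([0.3, -0.2], alpha=0.05) == [0.3, -0.2]  # n <= 2 guard


def test_remove_outliers_caps_removals():
    # ceil(0.2 * 10) = 2: at most two points may go even if more look extreme
    x = [0.0] * 8 + [5.0, 6.0, 7.0]
    out = remove_outliers(x, alpha=0.05)
    assert len(out) >= len(x) - math.ceil(0.2 * len(x))


def test_protein_replicate_ratio_weighted_geomean():
    prs = [PeptideRatio(2.0, 1.0), PeptideRatio(8.0, 3.0)]
    out = protein_replicate_ratio(prs, "P", 1)
    assert out.ratio == pytest.approx(2.0**2.5)  # exp((ln2 + 3 ln8)/4)
    assert out.n_peptides == 2


def test_protein_replicate_ratio_single_peptide_not_evaluable():
    assert protein_replicate_ratio([PeptideRatio(2.0, 1.0)], "P", 1) is None


def test_protein_replicate_ratio_two_peptide_erroneous_rule():
    prs = [PeptideRatio(1.1, 1.0), PeptideRatio(25.0, 1.0)]
    assert protein_replicate_ratio(prs, "P", 1) is None
    # same ratios with a third clean peptide: evaluable again
    prs3 = prs + [PeptideRatio(1.0, 1.0)]
    assert protein_replicate_ratio(prs3, "P", 1) is not None


@pytest.mark.parametrize(
    "triple,lo,hi",
    [
        ((0.28, 0.45, 0.61), 0.27, 0.66),
        ((0.36, 0.20, 0.32), 0.20, 0.40),
        ((0.37, 0.25, 0.56), 0.24, 0.59),
        ((0.49, 0.41, 0.39), 0.37, 0.49),
    ],
)
def test_geomean_ci_reproduces_published_ranges(triple, lo, hi):
    _, l, h = replicate_geomean_ci(triple)
    assert round(l, 2) == lo and round(h, 2) == hi


def test_geomean_ci_degenerate():
    assert replicate_geomean_ci((1.0, 1.0, 1.0)) == (1.0, 1.0, 1.0)


def test_geomean_ci_rejects_nonpositive():
    with pytest.raises(ValueError):
        replicate_geomean_ci((1.0, -0.5, 2.0))


@pytest.mark.parametrize(
    "lo,hi,expected",
    [(0.27, 0.66, "down"), (0.99, 2.76, "unchanged"), (1.5, 2.0, "up"),
     (0.3, 0.67, "down"), (0.9, 1.1, "unchanged")],
)
def test_classify_regulation(lo, hi, expected):
    assert classify_regulation(lo, hi) == expected


@given(r=st.floats(min_value=0.05, max_value=5.0))
@settings(max_examples=50, deadline=None)
def test_zero_variance_triple_classification(r):
    G, lo, hi = replicate_geomean_ci((r, r, r))
    cls = classify_regulation(lo, hi)
    if 0.67 < r < 1.5:
        assert cls == "unchanged"
    elif r <= 0.67:
        assert cls == "down"
    else:
        assert cls == "up"


def test_reference_table_bounds_within_printed_precision():
    """Recomputed CI bounds agree with the published ranges to the last
    printed digit for >= 90% of bounds (inputs are printed rounded)."""
    df = reference_ratio_table()
    ok = total = 0
    for row in df.itertuples():
        _, lo, hi = replicate_geomean_ci((row.r1, row.r2, row.r3))
        for got, pub in ((lo, row.published_low), (hi, row.published_high)):
            total += 1
            ok += abs(got - pub) <= 0.015
    assert ok / total >= 0.90


def _null_psms(n_proteins=30, n_peptides=4, fc=1.0, sigma=0.1, bias=None, seed=0):
    rng = np.random.default_rng(seed)
    tags = (113, 114, 115, 116, 117, 118, 119, 121)
    high = {114, 116, 118, 121}
    bias = bias or {t: 1.0 for t in tags}
    psms = []
    k = 0
    for p in range(n_proteins):
        for j in range(n_peptides):
            base = float(np.exp(rng.normal(math.log(1e4), 0.5)))
            intens = {}
            for t in tags:
                v = base * bias[t] * (fc if t in high else 1.0)
                intens[t] = v * float(np.exp(rng.normal(0, sigma)))
            k += 1
            psms.append(PSM(f"s{k}", f"PEP{p}X{j}K", f"P{p:03d}", intens))
    return psms


def test_quantify_null_experiment_no_calls():
    calls = quantify_experiment(_null_psms(fc=1.0))
    assert (calls.regulation == "unchanged").all()


def test_channel_scale_invariance():
    """Multiplying one channel by a constant changes nothing after
    median normalization."""
    psms = _null_psms(seed=3)
    scaled = [
        PSM(p.spectrum_id, p.peptide, p.source_id,
            {t: (v * 7.3 if t == 114 else v) for t, v in p.intensities.items()})
        for p in psms
    ]
    # unweighted ratios: the median absorbs the channel factor exactly
    a = quantify_experiment(psms, weighting="none").set_index("protein_id")
    b = quantify_experiment(scaled, weighting="none").set_index("protein_id")
    assert np.allclose(a.G, b.G, rtol=1e-9)
    assert (a.regulation == b.regulation).all()
    # intensity weighting: weights shift with the scaled channel, so the
    # invariance is approximate but the calls are unchanged
    aw = quantify_experiment(psms).set_index("protein_id")
    bw = quantify_experiment(scaled).set_index("protein_id")
    assert np.allclose(aw.G, bw.G, rtol=0.05)
    assert (aw.regulation == bw.regulation).all()


def test_down_regulated_protein_called(caplog):
    """FC 0.4 at sigma 0.15, 5 peptides, 3 replicates: classified down, and
    the call agrees with replicate_geomean_ci run by hand on the realized
    per-replicate ratios."""
    psms = _null_psms(n_proteins=20, n_peptides=5, fc=1.0, sigma=0.15, seed=1)
    down = _null_psms(n_proteins=1, n_peptides=5, fc=0.4, sigma=0.15, seed=11)
    down = [PSM(p.spectrum_id + "d", p.peptide + "R", "PDOWN", p.intensities) for p in down]
    calls = quantify_experiment(psms + down).set_index("protein_id")
    assert calls.loc["PDOWN", "regulation"] == "down"
    G, lo, hi = replicate_geomean_ci(
        [calls.loc["PDOWN", f"r{k}"] for k in (1, 2, 3)]
    )
    assert calls.loc["PDOWN", "G"] == pytest.approx(G)
    assert calls.loc["PDOWN", "ci_upper"] == pytest.approx(hi)


def test_missing_replicate_not_evaluable():
    psms = _null_psms(n_proteins=2, n_peptides=3)
    # kill channel 116 for protein P000: replicate 2 unusable
    crippled = [
        PSM(p.spectrum_id, p.peptide, p.source_id,
            {t: (0.0 if (t == 116 and p.source_id == "P000") else v)
             for t, v in p.intensities.items()})
        for p in psms
    ]
    calls = quantify_experiment(crippled).set_index("protein_id")
    assert calls.loc["P000", "regulation"] == "not_evaluable"
    assert calls.loc["P001", "regulation"] == "unchanged"


def test_reference_census_four_down_zero_up():
    df = reference_ratio_table()
    triples = {
        f"{r.identification}|{r.accession}": (r.r1, r.r2, r.r3) for r in df.itertuples()
    }
    calls = calls_from_replicate_ratios(triples)
    down_names = {c.protein_id.split("|")[0] for c in calls if c.regulation == "down"}
    assert down_names == {
        "30S ribosomal protein S7",
        "Histone H2A",
        "Histone H3",
        "Histone H4",
    }
    assert not any(c.regulation == "up" for c in calls)


def test_design_validation():
    with pytest.raises(ValueError):
        Design(replicate_pairs=((114, 113), (121, 119)))
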