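"""Z-scores, over-expression calls and gain/over-expression concordance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from progcnv import (
    CnvCallMatrix,
    ExpressionMatrix,
    PipelineThresholds,
    call_overexpressed,
    call_underexpressed,
    count_concordance,
    select_key_genes,
    z_scores,
)


def make_expr(values: np.ndarray, n_ref: int) -> ExpressionMatrix:
    n_genes, n_samples = values.shape
    cols = [f"t{j}" for j in range(n_samples - n_ref)] + [
        f"r{j}" for j in range(n_ref)
    ]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=[f"g{i}" for i in range(n_genes)],
                            columns=cols),
        reference_samples=cols[n_samples - n_ref:],
    )


def test_z_formula_simple_cases():
    # one gene, reference mean 4 and SD 3 by construction
    ref = np.array([1.0, 4.0, 7.0])
    assert np.isclose(np.mean(ref), 4.0) and np.isclose(np.std(ref, ddof=1), 3.0)
    expr = make_expr(np.array([[10.0, 4.0, 1.0, 4.0, 7.0]]), n_ref=3)
    z = z_scores(expr)
    assert z.loc["g0", "t0"] == pytest.approx(2.0)
    assert z.loc["g0", "t1"] == pytest.approx(0.0)  # x = mu


@pytest.mark.parametrize("seed", range(20))
def test_z_matches_direct_recomputation(seed):
    rng = np.random.default_rng(seed)
    values = rng.normal(5, 2, size=(20, 30))
    expr = make_expr(values, n_ref=10)
    z = z_scores(expr)
    mu = values[:, 20:].mean(axis=1)
    sigma = values[:, 20:].std(axis=1, ddof=1)
    expected = (values - mu[:, None]) / sigma[:, None]
    np.testing.assert_allclose(z.to_numpy(), expected, atol=1e-12, rtol=0)


def test_zero_sd_gene_excluded(caplog):
    values = np.array([[1.0, 2.0, 5.0, 5.0, 5.0],
                       [1.0, 2.0, 3.0, 4.0, 5.0]])
    expr = make_expr(values, n_ref=3)
    with caplog.at_level("WARNING"):
        z = z_scores(expr)
    assert list(z.index) == ["g1"]
    assert "zero/undefined reference SD" in caplog.text


def test_missing_values_propagate_and_call_false():
    values = np.array([[np.nan, 2.0, 1.0, 2.0, 3.0]])
    expr = make_expr(values, n_ref=3)
    z = z_scores(expr)
    assert np.isnan(z.loc["g0", "t0"])
    assert not call_overexpressed(z).loc["g0", "t0"]


@given(st.floats(0.1, 100.0), st.floats(-50.0, 50.0))
@settings(deadline=None, max_examples=50, derandomize=True)
def test_affine_invariance(a, b):
    """Rescaling x -> a*x + b (a>0) leaves Z-scores unchanged."""
    rng = np.random.default_rng(42)
    values = rng.normal(0, 1, size=(5, 20))
    z1 = z_scores(make_expr(values, n_ref=8))
    z2 = z_scores(make_expr(a * values + b, n_ref=8))
    np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-9)


def test_strict_threshold_boundaries():
    z = pd.DataFrame({"s": [2.1, 2.0, -2.5, -2.0]},
                     index=["a", "b", "c", "d"])
    over = call_overexpressed(z)
    under = call_underexpressed(z)
    assert over["s"].tolist() == [True, False, False, False]
    assert under["s"].tolist() == [False, False, True, False]


def _tiny_cnv(calls: dict[str, list[str]], samples: list[str]) -> CnvCallMatrix:
    return CnvCallMatrix(
        calls=pd.DataFrame.from_dict(calls, orient="index", columns=samples),
        cohorts=pd.Series("c", index=samples),
    )


def test_concordance_is_set_intersection():
    samples = ["s1", "s2", "s3", "s4", "s5"]
    cnv = _tiny_cnv({"A": ["GAIN", "GAIN", "GAIN", "NEUTRAL", "NEUTRAL"]},
                    samples)
    over = pd.DataFrame(
        [[False, True, True, True, False]], index=["A"], columns=samples
    )
    under = pd.DataFrame(False, index=["A"], columns=samples)
    rec = count_concordance(cnv, over, under)
    assert rec.loc["A", "n_gain"] == 3
    assert rec.loc["A", "n_gain_over"] == 2  # {s2, s3}


def test_concordance_disjoint_sets_is_zero():
    samples = ["s1", "s2", "s3"]
    cnv = _tiny_cnv({"A": ["GAIN", "NEUTRAL", "NEUTRAL"]}, samples)
    over = pd.DataFrame([[False, True, True]], index=["A"], columns=samples)
    rec = count_concordance(cnv, over)
    assert rec.loc["A", "n_gain_over"] == 0


def test_concordance_requires_shared_samples():
    cnv = _tiny_cnv({"A": ["GAIN"]}, ["s1"])
    over = pd.DataFrame([[True]], index=["A"], columns=["other"])
    with pytest.raises(ValueError, match="no shared samples"):
        count_concordance(cnv, over)


@pytest.mark.parametrize("seed", range(10))
def test_concordance_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    samples = [f"s{j}" for j in range(25)]
    genes = [f"g{i}" for i in range(8)]
    calls = rng.choice(["GAIN", "LOSS", "NEUTRAL"], size=(8, 25))
    cnv = CnvCallMatrix(
        calls=pd.DataFrame(calls, index=genes, columns=samples),
        cohorts=pd.Series("c", index=samples),
    )
    over = pd.DataFrame(rng.random((8, 25)) < 0.3, index=genes, columns=samples)
    under = pd.DataFrame(rng.random((8, 25)) < 0.3, index=genes,
                         columns=samples)
    rec = count_concordance(cnv, over, under)
    for i, g in enumerate(genes):
        n_go = sum(
            calls[i, j] == "GAIN" and over.iloc[i, j] for j in range(25)
        )
        n_lu = sum(
            calls[i, j] == "LOSS" and under.iloc[i, j] for j in range(25)
        )
        assert rec.loc[g, "n_gain_over"] == n_go
        assert rec.loc[g, "n_loss_under"] == n_lu
        assert rec.loc[g, "n_gain_over"] <= rec.loc[g, "n_gain"]
        assert rec.loc[g, "n_loss_under"] <= rec.loc[g, "n_loss"]


def test_key_gene_selection_boundaries_and_modes():
    records = pd.DataFrame(
        {
            "n_gain": [40, 40, 40],
            "n_gain_over": [21, 20, 25],
            "n_loss": [5, 5, 5],
            "n_loss_under": [0, 0, 1],
        },
        index=["keep", "boundary", "ratio_rich"],
    )
    assert select_key_genes(records) == {"keep", "ratio_rich"}
    # ratio mode: 21/0 -> inf, 20/0 -> inf, 25/1 = 25 (all > 20)
    assert select_key_genes(records, mode="ratio") == {
        "keep", "boundary", "ratio_rich"
    }
    with pytest.raises(ValueError):
        select_key_genes(records, mode="nope")


def test_n_gain_over_monotone_in_z_cutoff(small_bundle):
    z = z_scores(small_bundle.expression)
    cnv = small_bundle.cnv
    previous = None
    for cutoff in (1.0, 1.5, 2.0, 3.0):
        over = call_overexpressed(z, PipelineThresholds(z_cutoff=cutoff))
        rec = count_concordance(cnv, over)
        counts = rec["n_gain_over"]
        if previous is not None:
            assert (counts <= previous).all()
        previous = counts


def test_synthetic_truth_concordance_recovered(small_bundle):
    z = z_scores(small_bundle.expression)
    over = call_overexpressed(z)
    rec = count_concordance(small_bundle.cnv, over,
                            genes=small_bundle.truth.planted_genes)
    for gene, expected in small_bundle.truth.concordant_counts.items():
        assert rec.loc[gene, "n_gain_over"] == expected
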