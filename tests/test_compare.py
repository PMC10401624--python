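"""Fold changes, leg ratios, extensor/flexor classification and PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from antjump import (
    ValidationError,
    extensor_flexor_ratio,
    fold_change,
    leg_ratios,
    pair_comparisons,
    pc1_separation,
    run_pca,
)


def test_fold_change_arithmetic_and_reciprocity():
    assert fold_change(0.05, 0.01) == pytest.approx(5.0)
    assert fold_change(0.37, 0.37) == 1.0
    assert fold_change(0.054, 0.05) == pytest.approx(1.08)
    assert fold_change(3.0, 7.0) * fold_change(7.0, 3.0) == pytest.approx(1.0)


def test_pair_comparisons_requires_matching_muscles():
    with pytest.raises(ValidationError, match="mismatched"):
        pair_comparisons({"IIscm6": 1.0}, {"IIIscm6": 1.0}, "j", "n")
    out = pair_comparisons({"IIscm6": 0.1}, {"IIscm6": 0.02}, "j", "n")
    assert out[0].fold_change == pytest.approx(5.0)


@pytest.mark.parametrize(
    "ftm1, ftm2, ratio, label",
    [
        (1.0, 1.0, 1.0, "walking-leg-like"),
        (1.08, 1.0, 1.08, "walking-leg-like"),
        (0.38, 1.0, 0.38, "grasping-leg-like"),
    ],
)
def test_extensor_flexor_ratio(ftm1, ftm2, ratio, label):
    r, lab = extensor_flexor_ratio(ftm1 * 2e-10, ftm2 * 2e-10)
    assert r == pytest.approx(ratio)
    assert lab == label


@pytest.mark.parametrize(
    "front, middle, hind, body, ratio_string, pct",
    [
        (8.93, 10.03, 14.7, 9.24, "1:1.1:1.6", 159),     # long-hind jumper
        (8.46, 7.92, 10.91, 11.8, "1.1:1:1.4", 92),      # middle-shortest jumper
        (5.0, 5.0, 5.0, 5.0, "1:1:1", 100),              # degenerate equal legs
    ],
)
def test_leg_ratios_match_display_convention(front, middle, hind, body,
                                             ratio_string, pct):
    r = leg_ratios(front, middle, hind, body)
    assert r.ratio_string == ratio_string
    assert r.hind_pct_body == pct
    assert min(r.ratio_front, r.ratio_middle, r.ratio_hind) == 1.0


def test_leg_ratios_scale_invariance():
    a = leg_ratios(8.93, 10.03, 14.7, 9.24)
    b = leg_ratios(8.93 * 3, 10.03 * 3, 14.7 * 3, 9.24)
    assert (b.raw_front, b.raw_middle, b.raw_hind) == pytest.approx(
        (a.raw_front, a.raw_middle, a.raw_hind)
    )
    assert b.raw_hind_pct_body == pytest.approx(3 * a.raw_hind_pct_body)
    c = leg_ratios(8.93 * 3, 10.03 * 3, 14.7 * 3, 9.24 * 3)
    assert c.hind_pct_body == a.hind_pct_body


def _random_table(rng, n=8, p=10):
    data = rng.lognormal(0.0, 1.0, size=(n, p))
    return pd.DataFrame(data, columns=[f"v{j}" for j in range(p)],
                        index=[f"s{i}" for i in range(n)])


def test_pca_perfectly_correlated_variables():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    table = pd.DataFrame({"a": x, "b": 3 * x})
    res = run_pca(table)
    assert res.variance_explained[0] == pytest.approx(1.0, abs=1e-12)


def test_pca_matches_independent_eigen_oracle(rng):
    table = _random_table(rng, n=4, p=3)
    res = run_pca(table)
    # brute-force oracle: full eigen-decomposition of the correlation matrix
    z = (table - table.mean()) / table.std(ddof=1)
    eig = np.sort(np.linalg.eigvalsh(np.cov(z.to_numpy().T, ddof=1)))[::-1]
    assert np.allclose(res.variance_explained, eig / eig.sum(), atol=1e-10)


def test_pca_matches_sklearn(rng):
    sklearn_pca = pytest.importorskip("sklearn.decomposition").PCA
    table = _random_table(rng)
    res = run_pca(table)
    z = (table - table.mean()) / table.std(ddof=1)
    ref = sklearn_pca().fit(z.to_numpy())
    k = len(ref.explained_variance_ratio_)
    assert np.allclose(
        res.variance_explained[:k], ref.explained_variance_ratio_, atol=1e-10
    )


def test_pca_reconstruction_sign_convention_and_variance_sum(rng):
    table = _random_table(rng)
    res = run_pca(table)
    z = (table.to_numpy() - table.to_numpy().mean(0)) / table.to_numpy().std(
        0, ddof=1
    )
    assert np.allclose(res.scores @ res.loadings.T, z, atol=1e-8)
    assert np.allclose(res.loadings.T @ res.loadings, np.eye(res.loadings.shape[1]),
                       atol=1e-8)
    assert res.variance_explained.sum() == pytest.approx(1.0, abs=1e-8)
    assert np.all(np.diff(res.variance_explained) <= 1e-12)
    for j in range(res.loadings.shape[1]):
        k = np.argmax(np.abs(res.loadings[:, j]))
        assert res.loadings[k, j] > 0


def test_pca_rejects_bad_tables():
    x = np.array([1.0, 2.0, 3.0])
    with pytest.raises(ValidationError, match="constant"):
        run_pca(pd.DataFrame({"a": x, "b": [1.0, 1.0, 1.0]}))
    with pytest.raises(ValidationError, match="missing"):
        run_pca(pd.DataFrame({"a": x, "b": [1.0, np.nan, 2.0]}))
    with pytest.raises(ValidationError, match=">= 3"):
        run_pca(pd.DataFrame({"a": x[:2], "b": x[:2]}))


def test_two_independent_variables_split_variance(rng):
    n = 4000
    table = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
    res = run_pca(table)
    assert res.variance_explained[0] == pytest.approx(0.5, abs=0.05)


def test_pc1_separation_threshold_search():
    res = run_pca(pd.DataFrame(
        {"a": [-2.0, -1.0, 1.0, 2.0], "b": [-2.1, -0.9, 1.2, 1.9]},
        index=["j1", "j2", "n1", "n2"],
    ))
    labels = {"j1": True, "j2": True, "n1": False, "n2": False}
    separated, margin = pc1_separation(res, labels)
    assert separated and margin > 0
    interleaved = {"j1": True, "j2": False, "n1": True, "n2": False}
    separated, margin = pc1_separation(res, interleaved)
    assert not separated and margin == 0.0
    with pytest.raises(ValidationError):
        pc1_separation(res, {k: True for k in labels})


@settings(deadline=None, max_examples=30, derandomize=True)
@given(j=st.floats(0.01, 100.0), n=st.floats(0.01, 100.0))
def test_fold_change_reciprocal_property(j, n):
    assert fold_change(j, n) * fold_change(n, j) == pytest.approx(1.0, rel=1e-9)
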