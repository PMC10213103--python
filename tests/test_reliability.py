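"""ICC estimation, classification rules, screening, correlation and t-tests."""

import numpy as np
import pandas as pd
import pytest

from cbctrad import (
    ICCResult,
    MeasurementMatrix,
    classify_reliability,
    compare_cohorts,
    icc_absolute,
    reproducibility_screen,
    screen_features,
    volume_correlation,
)


def _anova_oracle(x):
    """Two-way ANOVA mean squares by explicit sums (independent of the package)."""
    n, k = x.shape
    gm = x.mean()
    ssr = sum(k * (x[i].mean() - gm) ** 2 for i in range(n))
    ssc = sum(n * (x[:, j].mean() - gm) ** 2 for j in range(k))
    sst = sum((v - gm) ** 2 for v in x.ravel())
    sse = sst - ssr - ssc
    return ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))


# --------------------------------------------------------------------- ICC ----

def test_identical_columns_give_perfect_icc():
    x = np.array([[1.0, 1.0], [3.0, 3.0], [5.0, 5.0]])
    for form in ("single", "average"):
        r = icc_absolute(x, form)
        assert r.icc == 1.0
        assert (r.ci_low, r.ci_high) == (1.0, 1.0)


def test_icc_single_matches_anova_oracle():
    x = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0], [7.0, 8.0]])
    msr, msc, mse = _anova_oracle(x)
    n, k = x.shape
    expected = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    r = icc_absolute(x, "single")
    assert r.icc == pytest.approx(expected, rel=1e-12)
    assert r.icc == pytest.approx(40 / 3 / (40 / 3 + 0.5 * 2), rel=1e-6)
    assert r.msr == pytest.approx(msr) and r.msc == pytest.approx(msc) and r.mse == pytest.approx(mse, abs=1e-12)


def test_icc_matches_pingouin_estimates_and_cis():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(3)
    for trial in range(10):
        n, k = rng.integers(5, 20), rng.integers(2, 4)
        subj = rng.normal(0, 1.0, size=(n, 1))
        rater = rng.normal(0, 0.3, size=(1, k))
        x = subj + rater + rng.normal(0, 0.5, size=(n, k))
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), k),
                "rater": np.tile(np.arange(k), n),
                "score": x.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        ref = ref.set_index("Type")
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        for form, typ in (("single", "ICC(A,1)"), ("average", "ICC(A,k)")):
            ours = icc_absolute(x, form)
            assert ours.icc == pytest.approx(ref.loc[typ, "ICC"], abs=1e-9)
            lo, hi = ref.loc[typ, ci_col]  # pingouin rounds bounds to 2 dp
            assert ours.ci_low == pytest.approx(lo, abs=1.5e-2)
            assert ours.ci_high == pytest.approx(hi, abs=1.5e-2)


def test_zero_subject_variance_gives_near_zero_icc():
    rng = np.random.default_rng(4)
    iccs = [
        icc_absolute(rng.normal(0, 1, size=(200, 2)), "single").icc for _ in range(100)
    ]
    assert abs(np.mean(iccs)) < 0.1


def test_icc_parameter_recovery():
    """Mean estimate within 0.03 of a true ICC of 0.8 (n=50, k=2, 200 replicates)."""
    rng = np.random.default_rng(5)
    true_icc = 0.8
    sd_subj, sd_err = 2.0, 1.0  # 4 / (4 + 1) = 0.8
    est = []
    for _ in range(200):
        x = sd_subj * rng.normal(size=(50, 1)) + sd_err * rng.normal(size=(50, 2))
        est.append(icc_absolute(x, "single").icc)
    assert np.mean(est) == pytest.approx(true_icc, abs=0.03)


def test_ci_coverage_93_to_97pct():
    """Nominal 95% CI covers a true ICC of 0.8 in 93-97% of 500 replicates (n=30, k=2)."""
    rng = np.random.default_rng(6)
    true_icc = 0.8
    hits = 0
    for _ in range(500):
        x = 2.0 * rng.normal(size=(30, 1)) + 1.0 * rng.normal(size=(30, 2))
        r = icc_absolute(x, "single")
        hits += r.ci_low <= true_icc <= r.ci_high
    assert 0.93 <= hits / 500 <= 0.97


def test_average_form_at_least_single_form():
    rng = np.random.default_rng(7)
    count = 0
    for _ in range(100):
        x = rng.normal(0, 1, size=(10, 1)) + 0.5 * rng.normal(size=(10, 3))
        s = icc_absolute(x, "single")
        a = icc_absolute(x, "average")
        if s.icc > 0:
            count += 1
            assert a.icc >= s.icc - 1e-12
    assert count > 50  # most draws have positive ICC under this model


def test_matrix_invariants():
    with pytest.raises(ValueError):
        icc_absolute(np.array([[1.0, 2.0]]))  # n < 2
    with pytest.raises(ValueError):
        MeasurementMatrix(np.array([[1.0], [2.0]]))  # k < 2
    with pytest.raises(ValueError):
        MeasurementMatrix(np.array([[1.0, np.nan], [2.0, 3.0]]))


# ----------------------------------------------------------- classification ----

def _res(icc, lo):
    return ICCResult(icc, lo, 1.0, "single", 1, 1, 1, 10, 2)


@pytest.mark.parametrize(
    "icc,lo,label",
    [
        (0.85, 0.75, "robust"),
        (0.85, 0.65, "reliable"),
        (0.80, 0.75, "not_reliable"),   # strict > 0.8
        (0.81, 0.70, "reliable"),       # strict > 0.7 on the lower bound
        (0.5, 0.2, "not_reliable"),
        (1.0, 1.0, "robust"),
    ],
)
def test_reliability_classification_rules(icc, lo, label):
    assert classify_reliability(_res(icc, lo)) == label


# ---------------------------------------------------------------- screening ----

def _long_table(values, condition="c"):
    """values: feature -> n x 2 matrix."""
    rows = []
    for f, x in values.items():
        for i in range(x.shape[0]):
            for j, rep in enumerate(("scan", "rescan")):
                rows.append(
                    {"roi_id": i, "condition": condition, "replicate": rep,
                     "feature_name": f, "value": x[i, j]}
                )
    return pd.DataFrame(rows)


def test_zero_noise_pair_all_nondegenerate_robust():
    rng = np.random.default_rng(8)
    base = rng.normal(size=6)
    table = _long_table(
        {
            "f_varying": np.column_stack([base, base]),      # identical raters
            "f_constant": np.zeros((6, 2)),                  # fully degenerate
        }
    )
    rep = screen_features(table)
    assert rep.robust_set("c") == {"f_varying"}
    assert rep.degenerate_set("c") == {"f_constant"}


def test_robust_set_intersection_algebra():
    rng = np.random.default_rng(9)
    base = rng.normal(size=8)
    good = np.column_stack([base, base])
    bad = rng.normal(size=(8, 2))
    t1 = _long_table({"a": good, "b": good, "c": good, "d": bad}, condition="x")
    t2 = _long_table({"a": bad, "b": good, "c": good, "d": good}, condition="y")
    rep = screen_features(pd.concat([t1, t2], ignore_index=True))
    assert rep.robust_set("x") == {"a", "b", "c"}
    assert rep.robust_set("y") == {"b", "c", "d"}
    assert rep.robust_intersection(["x", "y"]) == {"b", "c"}
    assert len(rep.robust_intersection()) == 2


def test_mismatched_feature_sets_rejected():
    rng = np.random.default_rng(10)
    base = rng.normal(size=4)
    t1 = _long_table({"a": np.column_stack([base, base])}, condition="x")
    t2 = _long_table({"b": np.column_stack([base, base])}, condition="y")
    with pytest.raises(ValueError, match="differ"):
        screen_features(pd.concat([t1, t2], ignore_index=True))


def test_reproducibility_screen_contract():
    rng = np.random.default_rng(11)
    rows = []
    base = rng.normal(size=8)
    for cond in (10, 25, 50, 100):
        for i in range(8):
            rows.append({"roi_id": i, "condition": cond, "feature_name": "f", "value": base[i]})
            rows.append({"roi_id": i, "condition": cond, "feature_name": "g",
                         "value": rng.normal()})
    rep = reproducibility_screen(pd.DataFrame(rows))
    frame = rep.to_frame()
    assert len(frame) == 2
    rec = {r.feature: r for r in rep.records}
    assert rec["f"].result.k == 4
    assert rec["f"].result.icc == 1.0
    assert rec["f"].result.form == "average"
    with pytest.raises(ValueError, match="2 conditions"):
        reproducibility_screen(pd.DataFrame(
            [{"roi_id": 0, "condition": 1, "feature_name": "f", "value": 0.1},
             {"roi_id": 1, "condition": 1, "feature_name": "f", "value": 0.2}]
        ))


# ------------------------------------------------------- volume correlation ----

def test_volume_correlation_rules():
    vols = np.array([27.68, 34.38, 41.71, 92.24, 237.5])
    rng = np.random.default_rng(12)
    table = pd.DataFrame(
        {
            "proportional": 2.0 * vols,
            "negative": -vols,
            "constant": np.ones(5),
            "random": rng.permutation(vols),
        }
    )
    out = volume_correlation(table, vols).set_index("feature_name")
    assert out.loc["proportional", "pearson_r"] == pytest.approx(1.0)
    assert bool(out.loc["proportional", "flagged"])
    assert out.loc["negative", "pearson_r"] == pytest.approx(-1.0)
    assert not out.loc["negative", "flagged"]        # signed rule as printed
    assert bool(out.loc["constant", "degenerate"])
    assert not out.loc["constant", "flagged"]
    # closed-form Pearson oracle for the permuted column
    y = table["random"].to_numpy()
    r_oracle = (np.mean(vols * y) - vols.mean() * y.mean()) / (vols.std() * y.std())
    assert out.loc["random", "pearson_r"] == pytest.approx(r_oracle, rel=1e-9)
    # absolute-value option flags the negative control
    out_abs = volume_correlation(table, vols, absolute=True).set_index("feature_name")
    assert bool(out_abs.loc["negative", "flagged"])


def test_volume_correlation_needs_three_volumes():
    with pytest.raises(ValueError):
        volume_correlation(pd.DataFrame({"f": [1.0, 2.0]}), np.array([1.0, 2.0]))


# --------------------------------------------------------- cohort comparison ----

def _cohort_table(a, b):
    rows = []
    for i, v in enumerate(a):
        rows.append({"cohort": "A", "subject": i, "f": v})
    for i, v in enumerate(b):
        rows.append({"cohort": "B", "subject": i, "f": v})
    return pd.DataFrame(rows)


def test_identical_arms_give_t0_p1():
    x = [1.0, 2.0, 3.0, 4.0]
    out = compare_cohorts(_cohort_table(x, x))
    assert out.loc[0, "t"] == 0.0
    assert out.loc[0, "p"] == 1.0
    assert not out.loc[0, "significant"]


def test_paired_t_matches_closed_form():
    a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
    out = compare_cohorts(_cohort_table(a, b))
    # differences all -1, sd 0 -> |t| = inf in theory; use a non-degenerate case
    a, b = [1.0, 2.0, 4.0], [2.0, 3.0, 4.0]
    out = compare_cohorts(_cohort_table(a, b))
    d = np.array(a) - np.array(b)
    t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
    from scipy import stats

    p_oracle = 2 * stats.t.sf(abs(t_oracle), len(d) - 1)
    assert out.loc[0, "t"] == pytest.approx(t_oracle, rel=1e-12)
    assert out.loc[0, "p"] == pytest.approx(p_oracle, rel=1e-12)


def test_null_cohort_rejects_about_5pct():
    """Independent null features: rejection fraction ~ alpha."""
    rng = np.random.default_rng(13)
    n_feat = 1000
    rows = []
    for arm in ("A", "B"):
        for s in range(9):
            row = {"cohort": arm, "subject": s}
            row.update({f"f{j}": rng.normal() for j in range(n_feat)})
            rows.append(row)
    out = compare_cohorts(pd.DataFrame(rows))
    frac = out["significant"].mean()
    assert frac == pytest.approx(0.05, abs=0.02)


def test_unequal_arms_rejected():
    t = _cohort_table([1.0, 2.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError, match="pairing"):
        compare_cohorts(t)
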