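"""Second-level inference tests: contrasts, difference statistic, filters."""

import numpy as np
import pandas as pd
import pytest

from dyadsync._bayes import PosteriorFit
from dyadsync.behaviour import ModelResult
from dyadsync.inference import (brain_behaviour_table, contrast_marginal,
                                fit_brain_behaviour_model,
                                fit_difference_model, fit_multivariate_model,
                                hbo_hbr_difference)

ROIS = ("LIFG", "LPFC", "MPFC", "RPFC", "RIFG")


def _simulated_roi_table(rng, n_per_group=8, group_shift=0.0,
                         ppt_sd=0.25, resid_sd=0.15, hbo_means=None):
    """Direct draw from the second-level generative model (no fNIRS chain)."""
    if hbo_means is None:
        hbo_means = {(roi, bt): 1.0 + 0.3 * i + (0.8 if bt == "Mixed" else 0)
                     for i, roi in enumerate(ROIS) for bt in ("AllGo", "Mixed")}
    rows = []
    for group, tag in (("Control", "C"), ("Synchronized", "S")):
        for k in range(n_per_group):
            pid = f"{tag}{k:02d}"
            u = {ch: (rng.normal(0, ppt_sd), rng.normal(0, ppt_sd))
                 for ch in ("hbo", "hbr")}
            for roi in ROIS:
                for bt in ("AllGo", "Mixed"):
                    m = 1.0 if bt == "Mixed" else 0.0
                    shift = group_shift if group == "Synchronized" else 0.0
                    mu_hbo = hbo_means[(roi, bt)] + shift
                    mu_hbr = -mu_hbo / 3
                    for chrom, mu, uu in (("hbo", mu_hbo, u["hbo"]),
                                          ("hbr", mu_hbr, u["hbr"])):
                        rows.append(dict(
                            participant_id=pid, group=group, roi=roi,
                            condition=bt, chromophore=chrom,
                            beta=mu + uu[0] + uu[1] * m
                            + rng.normal(0, resid_sd), se=0.1))
    return pd.DataFrame(rows)


def _toy_result(cell_draws: dict):
    """Assemble a ModelResult from hand-specified cell-mean draws."""
    labels = list(cell_draws)
    cells = np.column_stack([cell_draws[l] for l in labels])
    fit = PosteriorFit(draws={"cells": cells, "beta": cells},
                       diagnostics={"cell_labels": labels,
                                    "converged": True})
    return ModelResult(fit, {})


class TestMultivariateModel:
    def test_cell_means_recovered_and_covered(self, rng):
        df = _simulated_roi_table(rng)
        res = fit_multivariate_model(df, n_draws=600, seed=0)
        assert res.converged
        missed = 0
        errs = []
        for lab, s in res.summaries.items():
            chrom, roi, bt, _ = lab.split(":")
            base = (1.0 + 0.3 * ROIS.index(roi)
                    + (0.8 if bt == "Mixed" else 0.0))
            truth = base if chrom == "hbo" else -base / 3
            missed += not (s.hpd_lo <= truth <= s.hpd_hi)
            errs.append(abs(s.mean - truth))
        # cells share participant random effects, so coverage events are
        # strongly correlated: allow a clustered miss, but demand accuracy
        assert missed <= 12
        assert np.mean(errs) < 0.2

    def test_independent_outcomes_residual_correlation_near_zero(self, rng):
        df = _simulated_roi_table(rng)
        res = fit_multivariate_model(df, n_draws=400, seed=1)
        th = res.fit.draws["theta"]
        # residual cholesky off-diagonal vs diagonal: correlation draws
        l11 = np.exp(th[:, 0])
        l21 = th[:, 2]
        l22 = np.exp(th[:, 1])
        corr = l21 / np.sqrt(l21 ** 2 + l22 ** 2)
        lo, hi = np.quantile(corr, [0.025, 0.975])
        assert lo <= 0.0 <= hi

    def test_group_label_swap_flips_contrast_sign(self, rng):
        df = _simulated_roi_table(rng, group_shift=0.6)
        res = fit_multivariate_model(df, n_draws=400, seed=2)
        con = contrast_marginal(res, "control_minus_synchronized")
        swapped = df.copy()
        swapped["group"] = swapped["group"].map(
            {"Control": "Synchronized", "Synchronized": "Control"})
        res2 = fit_multivariate_model(swapped, n_draws=400, seed=2)
        con2 = contrast_marginal(res2, "control_minus_synchronized")
        merged = con.merge(con2, on=["roi", "block_type", "chromophore"])
        hbo = merged[merged["chromophore"] == "hbo"]
        np.testing.assert_allclose(hbo["beta_y"], -hbo["beta_x"], atol=0.15)

    def test_partial_pairs_accepted(self, rng):
        df = _simulated_roi_table(rng, n_per_group=5)
        # drop one participant's HbR rows in one ROI: partial information
        drop = ((df["participant_id"] == "C00") & (df["roi"] == "LIFG")
                & (df["chromophore"] == "hbr"))
        res = fit_multivariate_model(df[~drop], n_draws=200, seed=3)
        assert res.converged

    def test_too_few_participants_rejected(self, rng):
        df = _simulated_roi_table(rng, n_per_group=1)
        with pytest.raises(ValueError):
            fit_multivariate_model(df)


class TestContrastMarginal:
    def test_two_cell_toy_matches_hand_difference(self, rng):
        draws = {}
        for chrom in ("hbo", "hbr"):
            for roi in ROIS:
                for bt in ("AllGo", "Mixed"):
                    for g in ("Control", "Synchronized"):
                        mu = 1.0 if bt == "AllGo" else 0.25
                        draws[f"{chrom}:{roi}:{bt}:{g}"] = \
                            mu + 0.01 * rng.standard_normal(500)
        res = _toy_result(draws)
        con = contrast_marginal(res, "allgo_minus_mixed")
        expected = {}
        for roi in ROIS:
            d = 0.5 * (draws[f"hbo:{roi}:AllGo:Control"]
                       + draws[f"hbo:{roi}:AllGo:Synchronized"]
                       - draws[f"hbo:{roi}:Mixed:Control"]
                       - draws[f"hbo:{roi}:Mixed:Synchronized"])
            expected[roi] = d.mean()
        for _, r in con[con["chromophore"] == "hbo"].iterrows():
            assert r["beta"] == pytest.approx(expected[r["roi"]], rel=1e-9)
            assert r["flag"] == "substantial"  # gap 0.75 >> draw sd

    def test_equal_cells_contrast_zero_and_unflagged(self, rng):
        draws = {f"{c}:{roi}:{bt}:{g}": 0.02 * rng.standard_normal(400)
                 for c in ("hbo", "hbr") for roi in ROIS
                 for bt in ("AllGo", "Mixed")
                 for g in ("Control", "Synchronized")}
        con = contrast_marginal(_toy_result(draws), "allgo_minus_mixed")
        assert (con["flag"] == "none").all()
        assert (con["beta"].abs() < 0.01).all()

    def test_invariant_to_roi_level_reordering(self, rng):
        df = _simulated_roi_table(rng, n_per_group=5)
        res1 = fit_multivariate_model(df, n_draws=300, seed=4)
        reordered = df.sort_values("roi", ascending=False,
                                   kind="stable").reset_index(drop=True)
        res2 = fit_multivariate_model(reordered, n_draws=300, seed=4)
        c1 = contrast_marginal(res1, "allgo_minus_mixed")
        c2 = contrast_marginal(res2, "allgo_minus_mixed")
        m = c1.merge(c2, on=["roi", "chromophore"])
        np.testing.assert_allclose(m["beta_x"], m["beta_y"], atol=1e-6)

    def test_unknown_contrast_rejected(self, rng):
        draws = {f"hbo:{r}:{b}:{g}": rng.standard_normal(10)
                 for r in ROIS for b in ("AllGo", "Mixed")
                 for g in ("Control", "Synchronized")}
        with pytest.raises(ValueError):
            contrast_marginal(_toy_result(draws), "upside_down")


class TestHboHbrDifference:
    @pytest.mark.parametrize("hbo,hbr,d,klass", [
        (2.0, -1.0, 3.0, "negative"),
        (1.5, 1.5, 0.0, "positive"),
        (-2.0, 1.0, -3.0, "negative"),   # inverted response
        (0.5, 0.2, 0.3, "positive"),
    ])
    def test_definition_and_classification(self, hbo, hbr, d, klass):
        df = pd.DataFrame([
            dict(participant_id="p", group="Control", roi="LIFG",
                 condition="Mixed", chromophore="hbo", beta=hbo, se=0.1),
            dict(participant_id="p", group="Control", roi="LIFG",
                 condition="Mixed", chromophore="hbr", beta=hbr, se=0.1),
        ])
        out = hbo_hbr_difference(df)
        assert out["d"].iloc[0] == pytest.approx(d)
        assert out["corr_class"].iloc[0] == klass

    def test_unpaired_estimate_rejected(self):
        df = pd.DataFrame([dict(participant_id="p", group="Control",
                                roi="LIFG", condition="Mixed",
                                chromophore="hbo", beta=1.0, se=0.1)])
        with pytest.raises(ValueError, match="hb"):
            hbo_hbr_difference(df)


class TestDifferenceModel:
    def test_filter_never_adds_rows_and_null_case_agrees(self, rng):
        df = _simulated_roi_table(rng, n_per_group=6)
        diffs = hbo_hbr_difference(df)
        all_fit = fit_difference_model(diffs, "all", n_draws=300, seed=5)
        n_neg = (diffs["corr_class"] == "negative").sum()
        assert n_neg <= len(diffs)
        if n_neg == len(diffs):
            neg_fit = fit_difference_model(diffs, "negative_only",
                                           n_draws=300, seed=5)
            a = all_fit.fit.draws["cells"].mean(axis=0)
            b = neg_fit.fit.draws["cells"].mean(axis=0)
            np.testing.assert_allclose(a, b, atol=1e-9)

    def test_negative_filter_removes_systemic_contamination(self, rng):
        """Rows with sign-concordant HbO/HbR (systemic-like) pull the cell
        mean away from the cortical truth; the filter undoes the pull."""
        df = _simulated_roi_table(rng, n_per_group=10)
        diffs = hbo_hbr_difference(df)
        contaminated = diffs.copy()
        # inject systemic rows: HbO and HbR both strongly positive
        fake = diffs.iloc[:60].copy()
        fake["participant_id"] = "X" + fake["participant_id"]
        fake["hbo"] = 4.0
        fake["hbr"] = 3.0
        fake["d"] = 1.0
        fake["corr_class"] = "positive"
        contaminated = pd.concat([contaminated, fake], ignore_index=True)
        res_all = fit_difference_model(contaminated, "all", n_draws=300,
                                       seed=6)
        res_neg = fit_difference_model(contaminated, "negative_only",
                                       n_draws=300, seed=6)
        labels = res_all.fit.diagnostics["cell_labels"]
        truth = {}
        for lab in labels:
            roi, bt, _g = lab.split(":")
            base = (1.0 + 0.3 * ROIS.index(roi)
                    + (0.8 if bt == "Mixed" else 0.0))
            truth[lab] = base + base / 3  # d = hbo - hbr with hbr = -hbo/3
        err_all = np.mean([abs(res_all.summaries[l].mean - truth[l])
                           for l in labels if l in res_all.summaries])
        err_neg = np.mean([abs(res_neg.summaries[l].mean - truth[l])
                           for l in res_neg.fit.diagnostics["cell_labels"]])
        assert err_neg < err_all

    def test_all_negative_rows_makes_filters_identical(self, rng):
        df = _simulated_roi_table(rng, n_per_group=6)
        diffs = hbo_hbr_difference(df)
        diffs = diffs[diffs["corr_class"] == "negative"]
        a = fit_difference_model(diffs, "all", n_draws=200, seed=7)
        b = fit_difference_model(diffs, "negative_only", n_draws=200, seed=7)
        np.testing.assert_allclose(a.fit.draws["cells"],
                                   b.fit.draws["cells"])

    def test_filtered_empty_cell_suppresses_its_contrasts(self, rng):
        df = _simulated_roi_table(rng, n_per_group=3)
        diffs = hbo_hbr_difference(df)
        mask = ((diffs["roi"] == "LPFC") & (diffs["condition"] == "Mixed")
                & (diffs["group"] == "Control"))
        diffs.loc[mask, "corr_class"] = "positive"
        res = fit_difference_model(diffs, "negative_only", n_draws=100,
                                   seed=10)
        assert "LPFC:Mixed:Control" in res.fit.diagnostics["empty_cells"]
        con = contrast_marginal(res, "control_minus_synchronized")
        assert con[(con["roi"] == "LPFC")
                   & (con["block_type"] == "Mixed")].empty
        assert not con[(con["roi"] == "LIFG")
                       & (con["block_type"] == "Mixed")].empty

    def test_negative_fraction_reported(self, rng):
        df = _simulated_roi_table(rng, n_per_group=4)
        diffs = hbo_hbr_difference(df)
        res = fit_difference_model(diffs, "all", n_draws=100, seed=8)
        frac = res.fit.diagnostics["negative_fraction"]
        assert set(frac.columns) >= {"roi", "condition", "group", "neg"}
        assert frac["neg"].between(0, 1).all()


class TestBrainBehaviour:
    def _trials(self, rng, pids, rts, ces):
        rows = []
        for pid, rt, ce in zip(pids, rts, ces):
            group = "Control" if pid.startswith("C") else "Synchronized"
            for i in range(30):
                rows.append(dict(participant_id=pid, group=group,
                                 block_index=1, block_type="Mixed",
                                 trial_type="Go", responded=True,
                                 rt_ms=rt + rng.normal(0, 5)))
            for i in range(20):
                rows.append(dict(participant_id=pid, group=group,
                                 block_index=2, block_type="Mixed",
                                 trial_type="NoGo", responded=i < ce,
                                 rt_ms=rt if i < ce else np.nan))
        return pd.DataFrame(rows)

    def test_rt_slope_sign_convention(self, rng):
        """Larger difference d with larger reaction time gives a positive
        slope in that cell."""
        df = _simulated_roi_table(rng, n_per_group=10, resid_sd=0.05,
                                  ppt_sd=0.05)
        diffs = hbo_hbr_difference(df)
        pids = sorted(diffs["participant_id"].unique())
        rts = {pid: 250 + 10 * i for i, pid in enumerate(pids)}
        ces = {pid: 5 for pid in pids}
        slope = 0.02  # uM per ms, injected in one cell only
        mask = ((diffs["roi"] == "LIFG") & (diffs["condition"] == "Mixed")
                & (diffs["group"] == "Control"))
        diffs.loc[mask, "d"] += slope * (
            diffs.loc[mask, "participant_id"].map(rts) - 300)
        trials = self._trials(rng, pids, [rts[p] for p in pids],
                              [ces[p] for p in pids])
        res = fit_brain_behaviour_model(diffs, trials, n_draws=400, seed=9)
        tab = brain_behaviour_table(res)
        hit = tab[(tab["roi"] == "LIFG") & (tab["block_type"] == "Mixed")
                  & (tab["group"] == "Control")]
        assert hit["rt_beta"].iloc[0] == pytest.approx(slope, abs=0.01)
        others = tab[~((tab["roi"] == "LIFG") & (tab["block_type"] == "Mixed")
                       & (tab["group"] == "Control"))]
        assert others["rt_beta"].abs().max() < slope / 2

    def test_join_failure_reports_participant(self, rng):
        df = _simulated_roi_table(rng, n_per_group=3)
        diffs = hbo_hbr_difference(df)
        pids = sorted(diffs["participant_id"].unique())[:-1]  # drop one
        trials = self._trials(rng, pids, [300] * len(pids), [4] * len(pids))
        with pytest.raises(ValueError, match="S02"):
            fit_brain_behaviour_model(diffs, trials)
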