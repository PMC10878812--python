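"""Second-level Bayesian inference on ROI-level haemodynamic amplitudes.

Takes the first-level ROI estimates (per participant, ROI, block type and
chromophore) and fits:

* a bivariate Gaussian model of (HbO, HbR) with fixed effects for every
  BlockType x ROI x Group cell, participant random intercepts and
  block-type slopes shared (correlated) across the two outcomes, and a
  free residual HbO-HbR correlation;
* the HbO-HbR difference model — the derived statistic d = beta_HbO -
  beta_HbR per (participant, ROI, block type), optionally restricted to
  "negatively correlated" pairs (sign-discordant HbO/HbR estimates,
  which are the pairs most likely to reflect cortical rather than
  systemic physiology);
* the brain-behaviour model relating the difference statistic to each
  participant's mean reaction time and commission-error count within
  every ROI x block type x group cell.

Marginal contrasts are formed on posterior cell-mean draws with equal
weights (balanced design): AllGo minus Mixed per ROI (groups combined)
and Control minus Synchronized per ROI and block type.  Effects whose
95% HPD excludes zero are flagged "substantial"; those excluding zero
at 90% but not 95% are flagged "trend".
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from ._bayes import PosteriorSummary, fit_lmm, hpd_interval
from .behaviour import ModelResult

__all__ = [
    "CELL_FACTORS",
    "fit_multivariate_model",
    "contrast_marginal",
    "hbo_hbr_difference",
    "fit_difference_model",
    "fit_brain_behaviour_model",
]

ROIS = ("LIFG", "LPFC", "MPFC", "RPFC", "RIFG")
BLOCK_TYPES = ("AllGo", "Mixed")
GROUPS = ("Control", "Synchronized")
CHROMOPHORES = ("hbo", "hbr")
CELL_FACTORS = (BLOCK_TYPES, ROIS, GROUPS)

_REQ_COLS = {"participant_id", "group", "roi", "condition", "chromophore",
             "beta", "se"}


def _check_roi_table(df: pd.DataFrame):
    missing = _REQ_COLS - set(df.columns)
    if missing:
        raise ValueError(f"ROI-estimate table missing columns: {sorted(missing)}")


def _cell_label(chrom, roi, bt, group):
    return f"{chrom}:{roi}:{bt}:{group}" if chrom else f"{roi}:{bt}:{group}"


def _cell_design(df: pd.DataFrame, with_chrom: bool):
    """One-hot cell-mean design; returns (X, labels)."""
    labels = []
    cols = []
    chroms = CHROMOPHORES if with_chrom else (None,)
    for chrom in chroms:
        for roi in ROIS:
            for bt in BLOCK_TYPES:
                for group in GROUPS:
                    ind = ((df["roi"] == roi) & (df["condition"] == bt)
                           & (df["group"] == group))
                    if with_chrom:
                        ind &= df["chromophore"] == chrom
                    labels.append(_cell_label(chrom, roi, bt, group))
                    cols.append(ind.to_numpy(float))
    return np.column_stack(cols), labels


# --------------------------------------------------------------------------
# Multivariate (HbO, HbR) model
# --------------------------------------------------------------------------

def fit_multivariate_model(roi_estimates: pd.DataFrame, n_draws: int = 2000,
                           seed: int = 0) -> ModelResult:
    """Bivariate hierarchical Gaussian model of ROI amplitudes.

    ``roi_estimates`` needs columns participant_id, group, roi, condition
    (block type), chromophore ('hbo'/'hbr'), beta, se.  Rows with a
    missing chromophore partner still contribute (partial pairs are
    marginalized, never imputed).  Returns cell-mean draws under
    ``fit.draws['cells']`` with labels ``fit.diagnostics['cell_labels']``.
    """
    df = roi_estimates.copy()
    _check_roi_table(df)
    if df.groupby("group")["participant_id"].nunique().min() < 2:
        raise ValueError("need at least two participants per group")
    X, labels = _cell_design(df, with_chrom=True)
    present = X.sum(axis=0) > 0
    if not present.all():
        absent = [l for l, p in zip(labels, present) if not p]
        raise ValueError(f"empty design cells: {absent}")
    is_hbr = (df["chromophore"] == "hbr").to_numpy(float)
    is_hbo = 1.0 - is_hbr
    bt = (df["condition"] == "Mixed").to_numpy(float)
    # random effects: (intercept, slope) per chromophore, correlated (q=4)
    Z = np.column_stack([is_hbo, is_hbo * bt, is_hbr, is_hbr * bt])
    pairs = (df["participant_id"].astype(str) + "|" + df["roi"].astype(str)
             + "|" + df["condition"].astype(str)).to_numpy()
    scale = max(float(df["beta"].abs().mean()), 0.1)
    fit = fit_lmm(df["beta"].to_numpy(), X,
                  df["participant_id"].to_numpy(), Z,
                  outcome=is_hbr.astype(int), pairs=pairs,
                  beta_prior_sd=10.0 * scale, resid_scale=scale,
                  re_scale=0.5 * scale, n_draws=n_draws, seed=seed)
    fit.draws["cells"] = fit.draws["beta"]
    fit.diagnostics["cell_labels"] = labels
    summaries = {}
    if fit.converged:
        summaries = {l: PosteriorSummary.from_draws(l, fit.draws["beta"][:, j],
                                                    scale="uM")
                     for j, l in enumerate(labels)}
    return ModelResult(fit, summaries)


# --------------------------------------------------------------------------
# Marginal contrasts
# --------------------------------------------------------------------------

def _flag(draws) -> str:
    lo95, hi95 = hpd_interval(draws, 0.95)
    if lo95 > 0 or hi95 < 0:
        return "substantial"
    lo90, hi90 = hpd_interval(draws, 0.90)
    if lo90 > 0 or hi90 < 0:
        return "trend"
    return "none"


def contrast_marginal(result: ModelResult, contrast: str) -> pd.DataFrame:
    """Marginal contrasts from posterior cell-mean draws.

    ``contrast`` is ``"allgo_minus_mixed"`` (per ROI, groups averaged
    with equal weights; positive = AllGo more positive) or
    ``"control_minus_synchronized"`` (per ROI and block type; positive =
    Control more positive).  Returns a tidy table with posterior mean,
    95% HPD and a substantial/trend/none flag per chromophore (or the
    difference measure, for univariate fits).
    """
    fit = result.fit
    labels = fit.diagnostics["cell_labels"]
    empty = set(fit.diagnostics.get("empty_cells", []))
    cells = fit.draws["cells"]
    lab_idx = {l: j for j, l in enumerate(labels)}
    with_chrom = ":" in labels[0] and labels[0].split(":")[0] in CHROMOPHORES
    chroms = CHROMOPHORES if with_chrom else ("diff",)

    def cell(chrom, roi, btv, group):
        key = _cell_label(chrom if with_chrom else None, roi, btv, group)
        if key not in lab_idx:
            if key in empty:
                return None  # filtered-empty cell: contrast suppressed
            raise KeyError(f"unknown cell: {key}")
        return cells[:, lab_idx[key]]

    rows = []
    if contrast == "allgo_minus_mixed":
        for chrom in chroms:
            for roi in ROIS:
                parts = [(cell(chrom, roi, "AllGo", g),
                          cell(chrom, roi, "Mixed", g)) for g in GROUPS]
                if any(a is None or m is None for a, m in parts):
                    continue
                d = 0.5 * sum(a - m for a, m in parts)
                lo, hi = hpd_interval(d, 0.95)
                rows.append(dict(contrast="AllGo-Mixed", roi=roi,
                                 block_type="both", chromophore=chrom,
                                 beta=float(np.mean(d)), hpd_lo=lo, hpd_hi=hi,
                                 flag=_flag(d)))
    elif contrast == "control_minus_synchronized":
        for chrom in chroms:
            for roi in ROIS:
                for btv in BLOCK_TYPES:
                    c = cell(chrom, roi, btv, "Control")
                    s = cell(chrom, roi, btv, "Synchronized")
                    if c is None or s is None:
                        continue
                    d = c - s
                    lo, hi = hpd_interval(d, 0.95)
                    rows.append(dict(contrast="Control-Synchronized",
                                     roi=roi, block_type=btv,
                                     chromophore=chrom,
                                     beta=float(np.mean(d)), hpd_lo=lo,
                                     hpd_hi=hi, flag=_flag(d)))
    else:
        raise ValueError(f"unknown contrast: {contrast!r}")
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# HbO-HbR difference
# --------------------------------------------------------------------------

def hbo_hbr_difference(roi_estimates: pd.DataFrame) -> pd.DataFrame:
    """Derived difference d = beta_HbO - beta_HbR per (participant, ROI,
    block type), with a correlation class per pair.

    A pair is classed 'negative' (cortical-like) when the HbO and HbR
    point estimates have opposite signs, 'positive' (systemic-like)
    otherwise; positive d corresponds to a canonical response, negative
    d to an inverted one.
    """
    df = roi_estimates.copy()
    _check_roi_table(df)
    wide = df.pivot_table(index=["participant_id", "group", "roi",
                                 "condition"],
                          columns="chromophore", values="beta",
                          aggfunc="first")
    if "hbo" not in wide.columns or "hbr" not in wide.columns:
        raise ValueError("need both 'hbo' and 'hbr' estimates")
    unpaired = wide["hbo"].isna() | wide["hbr"].isna()
    if unpaired.any():
        raise ValueError(
            f"unpaired HbO/HbR estimates for {int(unpaired.sum())} rows, "
            f"e.g. {wide.index[unpaired][:3].tolist()}")
    out = wide.reset_index()
    out["d"] = out["hbo"] - out["hbr"]
    out["corr_class"] = np.where(out["hbo"] * out["hbr"] < 0,
                                 "negative", "positive")
    return out[["participant_id", "group", "roi", "condition", "hbo", "hbr",
                "d", "corr_class"]]


def fit_difference_model(diffs: pd.DataFrame, filter: str = "all",
                         n_draws: int = 2000, seed: int = 0) -> ModelResult:
    """Hierarchical Gaussian model of the HbO-HbR difference.

    ``filter='negative_only'`` retains sign-discordant pairs only (the
    conservative analysis excluding systemic-like responses).  Cells left
    empty by the filter are flagged in ``fit.diagnostics['empty_cells']``
    and their contrasts suppressed.  The fraction of negative-class rows
    per cell is reported in ``fit.diagnostics['negative_fraction']``.
    """
    if filter not in ("all", "negative_only"):
        raise ValueError("filter must be 'all' or 'negative_only'")
    df = diffs.copy()
    frac = (df.assign(neg=df["corr_class"] == "negative")
            .groupby(["roi", "condition", "group"])["neg"].mean())
    if filter == "negative_only":
        df = df[df["corr_class"] == "negative"].reset_index(drop=True)
    if df.empty:
        raise ValueError("filter removed every row")
    X, labels = _cell_design(df.rename(columns={"condition": "condition"}),
                             with_chrom=False)
    present = X.sum(axis=0) > 0
    empty = [l for l, p in zip(labels, present) if not p]
    keep = [j for j, p in enumerate(present) if p]
    X = X[:, keep]
    labels_kept = [labels[j] for j in keep]
    bt = (df["condition"] == "Mixed").to_numpy(float)
    Z = np.column_stack([np.ones(len(df)), bt])
    scale = max(float(df["d"].abs().mean()), 0.1)
    fit = fit_lmm(df["d"].to_numpy(), X, df["participant_id"].to_numpy(), Z,
                  beta_prior_sd=10.0 * scale, resid_scale=scale,
                  re_scale=0.5 * scale, n_draws=n_draws, seed=seed)
    fit.draws["cells"] = fit.draws["beta"]
    fit.diagnostics["cell_labels"] = labels_kept
    fit.diagnostics["empty_cells"] = empty
    fit.diagnostics["negative_fraction"] = frac.reset_index()
    summaries = {}
    if fit.converged:
        summaries = {l: PosteriorSummary.from_draws(l, fit.draws["beta"][:, j],
                                                    scale="uM")
                     for j, l in enumerate(labels_kept)}
    return ModelResult(fit, summaries)


# --------------------------------------------------------------------------
# Brain-behaviour model
# --------------------------------------------------------------------------

def fit_brain_behaviour_model(diffs: pd.DataFrame, trials: pd.DataFrame,
                              n_draws: int = 2000,
                              seed: int = 0) -> ModelResult:
    """HbO-HbR difference regressed on behaviour within every cell.

    Joins each participant's mean Go-trial reaction time (ms) and
    Mixed-block commission-error count to their difference estimates and
    fits, per ROI x block type x group cell, an intercept plus slopes on
    the two covariates and their product (covariates standardized
    internally; slopes reported per original units).  Returns a
    Table-style summary under ``result.table``-like access via
    :func:`brain_behaviour_table`.
    """
    from .behaviour import parse_trials

    trials = parse_trials(trials)
    go = trials[(trials["trial_type"] == "Go") & trials["responded"]]
    rt = go.groupby("participant_id")["rt_ms"].mean().rename("mean_rt")
    nogo = trials[trials["trial_type"] == "NoGo"]
    ce = nogo.groupby("participant_id")["responded"].sum().rename("ce")
    df = diffs.join(rt, on="participant_id").join(ce, on="participant_id")
    bad = df["mean_rt"].isna() | df["ce"].isna()
    if bad.any():
        missing = sorted(df.loc[bad, "participant_id"].unique())
        raise ValueError(f"no behavioural data for participants: {missing}")
    rt_mu, rt_sd = df["mean_rt"].mean(), max(df["mean_rt"].std(), 1e-9)
    ce_mu, ce_sd = df["ce"].mean(), max(df["ce"].std(), 1e-9)
    rt_z = ((df["mean_rt"] - rt_mu) / rt_sd).to_numpy()
    ce_z = ((df["ce"] - ce_mu) / ce_sd).to_numpy()
    cells, labels = _cell_design(df, with_chrom=False)
    X_cols, col_names = [], []
    for j, lab in enumerate(labels):
        ind = cells[:, j]
        for term, v in (("1", np.ones(len(df))), ("rt", rt_z),
                        ("ce", ce_z), ("rt_x_ce", rt_z * ce_z)):
            X_cols.append(ind * v)
            col_names.append(f"{lab}:{term}")
    X = np.column_stack(X_cols)
    bt = (df["condition"] == "Mixed").to_numpy(float)
    Z = np.column_stack([np.ones(len(df)), bt])
    scale = max(float(df["d"].abs().mean()), 0.1)
    fit = fit_lmm(df["d"].to_numpy(), X, df["participant_id"].to_numpy(), Z,
                  beta_prior_sd=10.0 * scale, resid_scale=scale,
                  re_scale=0.5 * scale, n_draws=n_draws, seed=seed)
    fit.diagnostics["cell_labels"] = labels
    fit.diagnostics["col_names"] = col_names
    fit.diagnostics["standardizers"] = dict(rt_sd=rt_sd, ce_sd=ce_sd)
    summaries = {}
    if fit.converged:
        idx = {nm: j for j, nm in enumerate(col_names)}
        for lab in labels:
            # slopes per original units at the other covariate's mean
            rt_slope = fit.draws["beta"][:, idx[f"{lab}:rt"]] / rt_sd
            ce_slope = fit.draws["beta"][:, idx[f"{lab}:ce"]] / ce_sd
            summaries[f"{lab}:rt_slope"] = PosteriorSummary.from_draws(
                f"{lab}:rt_slope", rt_slope, scale="uM-per-ms")
            summaries[f"{lab}:ce_slope"] = PosteriorSummary.from_draws(
                f"{lab}:ce_slope", ce_slope, scale="uM-per-error")
    return ModelResult(fit, summaries)


def brain_behaviour_table(result: ModelResult) -> pd.DataFrame:
    """Table-4-style layout: one row per ROI x block type x group with RT
    and commission-error slopes, HPDs and flags."""
    rows = []
    for roi, btv, group in itertools.product(ROIS, BLOCK_TYPES, GROUPS):
        lab = _cell_label(None, roi, btv, group)
        r = {"roi": roi, "block_type": btv, "group": group}
        for short, key in (("rt", "rt_slope"), ("ce", "ce_slope")):
            s = result.summaries.get(f"{lab}:{key}")
            if s is None:
                continue
            draws_key = f"{lab}:{key}"
            r[f"{short}_beta"] = s.mean
            r[f"{short}_hpd_lo"] = s.hpd_lo
            r[f"{short}_hpd_hi"] = s.hpd_hi
            width95 = (s.hpd_lo > 0) or (s.hpd_hi < 0)
            r[f"{short}_flag"] = "substantial" if width95 else "none"
        rows.append(r)
    return pd.DataFrame(rows)
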