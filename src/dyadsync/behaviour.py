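"""Go/NoGo behavioural analysis: parsing, descriptives and hierarchical fits.

Reaction times on responded Go trials are modelled on the log scale
(lognormal likelihood) with fixed effects of group, block type and their
interaction (treatment coding: Control = 0, Synchronized = 1; AllGo = 0,
Mixed = 1) and correlated participant random intercepts and block-type
slopes:

    log RT ~ 1 + Group * BlockType + (1 + BlockType | ID)

Commission errors (responses on NoGo trials) are summed per participant
and modelled as Poisson counts with a log-exposure offset and a
participant-level random intercept:

    CE ~ 1 + Group + (1 | ID)

Effects are reported both on the model scale and on the response scale
(ms, or errors per 80 NoGo trials — the full task's exposure) as
differences of posterior marginal means.  Credible intervals are 95%
highest-posterior-density intervals throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._bayes import (PosteriorFit, PosteriorSummary, compare_loo, fit_lmm,
                     fit_poisson, hpd_interval)

__all__ = [
    "TRIAL_COLUMNS",
    "parse_trials",
    "QuestionnaireResponse",
    "score_extraversion",
    "descriptive_stats",
    "ModelResult",
    "fit_rt_model",
    "fit_ce_model",
    "fit_rt_ce_model",
    "hpd_interval",
    "compare_loo",
]

TRIAL_COLUMNS = ("participant_id", "group", "block_index", "block_type",
                 "trial_type", "responded", "rt_ms")
GROUPS = ("Control", "Synchronized")
BLOCK_TYPES = ("AllGo", "Mixed")
#: NoGo trials in the full 40-block task; the exposure used for
#: count-scale reporting so estimates are comparable across task lengths.
FULL_TASK_NOGO = 80
RESPONSE_WINDOW_MS = 1000.0


# --------------------------------------------------------------------------
# Parsing and scoring
# --------------------------------------------------------------------------

def parse_trials(source) -> pd.DataFrame:
    """Load and validate a trial table (CSV path or DataFrame).

    Rows violating the trial invariants (NoGo outside Mixed blocks, RT
    outside (0, 1000] ms, RT present without a response or vice versa)
    are dropped with a warning listing their line numbers; a missing
    required column raises.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    df["responded"] = df["responded"].astype(bool)
    df["rt_ms"] = pd.to_numeric(df["rt_ms"], errors="coerce")
    bad = pd.Series(False, index=df.index)
    bad |= ~df["group"].isin(GROUPS)
    bad |= ~df["block_type"].isin(BLOCK_TYPES)
    bad |= ~df["trial_type"].isin(("Go", "NoGo"))
    bad |= (df["trial_type"] == "NoGo") & (df["block_type"] != "Mixed")
    has_rt = df["rt_ms"].notna()
    bad |= df["responded"] & (~has_rt | (df["rt_ms"] <= 0)
                              | (df["rt_ms"] > RESPONSE_WINDOW_MS))
    bad |= ~df["responded"] & has_rt
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # 1-based + header line
        shown = ", ".join(map(str, lines[:20]))
        more = "" if len(lines) <= 20 else f" (+{len(lines) - 20} more)"
        warnings.warn(f"rejected {len(lines)} invalid trial rows "
                      f"at lines {shown}{more}")
    return df[~bad].reset_index(drop=True)


@dataclass
class QuestionnaireResponse:
    """Extraversion (10 items, Likert 1-5) and self-esteem (10 items,
    Likert 0-3) responses with per-item reverse-scoring flags.

    Default flags mark the second half of each scale as negatively
    worded (5 positive + 5 reversed items per scale).
    """

    extraversion: tuple
    self_esteem: tuple
    extraversion_reversed: tuple = field(
        default=(False,) * 5 + (True,) * 5)
    self_esteem_reversed: tuple = field(
        default=(False,) * 5 + (True,) * 5)

    def __post_init__(self):
        if len(self.extraversion) != 10 or len(self.self_esteem) != 10:
            raise ValueError("both scales require exactly 10 items")
        if any(v is None for v in self.extraversion + self.self_esteem):
            raise ValueError("missing questionnaire item")
        if not all(1 <= v <= 5 for v in self.extraversion):
            raise ValueError("extraversion items must be in 1..5")
        if not all(0 <= v <= 3 for v in self.self_esteem):
            raise ValueError("self-esteem items must be in 0..3")


def score_extraversion(resp: QuestionnaireResponse) -> int:
    """Summed extraversion + self-esteem score with reversed items
    mapped v -> 6 - v (extraversion) and v -> 3 - v (self-esteem)."""
    ext = sum(6 - v if rev else v
              for v, rev in zip(resp.extraversion, resp.extraversion_reversed))
    se = sum(3 - v if rev else v
             for v, rev in zip(resp.self_esteem, resp.self_esteem_reversed))
    return int(ext + se)


# --------------------------------------------------------------------------
# Descriptives
# --------------------------------------------------------------------------

def descriptive_stats(trials: pd.DataFrame) -> dict:
    """Group/block-type descriptives.

    Reaction times: mean and sd across participants of each participant's
    mean RT over responded Go trials.  Commission errors: mean and sd
    across participants of each participant's count of responded NoGo
    trials in Mixed blocks.
    """
    go = trials[(trials["trial_type"] == "Go") & trials["responded"]]
    per_p = (go.groupby(["group", "block_type", "participant_id"])["rt_ms"]
             .mean().reset_index())
    rt = (per_p.groupby(["group", "block_type"])["rt_ms"]
          .agg(mean="mean", sd="std").reset_index())
    nogo = trials[trials["trial_type"] == "NoGo"]
    ce_p = (nogo.groupby(["group", "participant_id"])["responded"]
            .sum().reset_index(name="commission_errors"))
    ce = (ce_p.groupby("group")["commission_errors"]
          .agg(mean="mean", sd="std").reset_index())
    ce["block_type"] = "Mixed"
    return {"reaction_times": rt, "commission_errors": ce,
            "commission_errors_per_participant": ce_p}


# --------------------------------------------------------------------------
# Model fits
# --------------------------------------------------------------------------

@dataclass
class ModelResult:
    """A fitted model: posterior draws plus named effect summaries."""

    fit: PosteriorFit
    summaries: dict

    @property
    def converged(self) -> bool:
        return self.fit.converged

    def effects_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.as_dict() for s in self.summaries.values()])


def _withheld(fit) -> bool:
    if not fit.converged:
        warnings.warn("sampler/optimizer did not converge; "
                      "effect summaries withheld")
        return True
    return False


def _design_rt(go: pd.DataFrame):
    g = (go["group"] == "Synchronized").to_numpy(float)
    bt = (go["block_type"] == "Mixed").to_numpy(float)
    X = np.column_stack([np.ones(len(go)), g, bt, g * bt])
    Z = np.column_stack([np.ones(len(go)), bt])
    return X, Z


def _rt_cell_ms(fit):
    """Posterior draws of marginal-mean RT (ms) per (group, block type).

    The marginal mean over the lognormal link includes the residual and
    random-effect variance for the cell: exp(eta + (sigma^2 + var_u)/2).
    """
    b = fit.draws["beta"]
    sig2 = fit.draws["sigma"] ** 2
    S = fit.draws["re_cov"]
    var_allgo = S[:, 0, 0]
    var_mixed = S[:, 0, 0] + 2 * S[:, 0, 1] + S[:, 1, 1]
    eta = {("Control", "AllGo"): b[:, 0],
           ("Synchronized", "AllGo"): b[:, 0] + b[:, 1],
           ("Control", "Mixed"): b[:, 0] + b[:, 2],
           ("Synchronized", "Mixed"): b[:, 0] + b[:, 1] + b[:, 2] + b[:, 3]}
    var_u = {"AllGo": var_allgo, "Mixed": var_mixed}
    return {cell: np.exp(e + 0.5 * (sig2 + var_u[cell[1]]))
            for cell, e in eta.items()}


def fit_rt_model(trials: pd.DataFrame, n_draws: int = 2000,
                 seed: int = 0) -> ModelResult:
    """Hierarchical lognormal RT model on responded Go trials.

    Reports the treatment-coded coefficients on the log scale and, on
    the ms scale, the block-type effect (Mixed minus AllGo, groups
    averaged), the group effect (Synchronized minus Control, block types
    averaged) and their interaction, as differences of posterior
    marginal means.
    """
    trials = parse_trials(trials)
    go = trials[(trials["trial_type"] == "Go") & trials["responded"]]
    if go["participant_id"].nunique() < 4:
        raise ValueError("need at least two participants per group")
    X, Z = _design_rt(go)
    y = np.log(go["rt_ms"].to_numpy())
    fit = fit_lmm(y, X, go["participant_id"].to_numpy(), Z,
                  beta_prior_sd=10.0, resid_scale=0.2, re_scale=0.05,
                  n_draws=n_draws, seed=seed,
                  coef_names=("intercept", "group", "block_type",
                              "group_x_block"))
    cells = _rt_cell_ms(fit)
    block_ms = 0.5 * (cells[("Control", "Mixed")] - cells[("Control", "AllGo")]
                      + cells[("Synchronized", "Mixed")]
                      - cells[("Synchronized", "AllGo")])
    group_ms = 0.5 * (cells[("Synchronized", "AllGo")]
                      - cells[("Control", "AllGo")]
                      + cells[("Synchronized", "Mixed")]
                      - cells[("Control", "Mixed")])
    inter_ms = (cells[("Synchronized", "Mixed")]
                - cells[("Synchronized", "AllGo")]
                - cells[("Control", "Mixed")] + cells[("Control", "AllGo")])
    fit.draws["block_effect_ms"] = block_ms
    fit.draws["group_effect_ms"] = group_ms
    fit.draws["interaction_ms"] = inter_ms
    for (gname, btname), d in cells.items():
        fit.draws[f"mean_ms[{gname},{btname}]"] = d
    if _withheld(fit):
        return ModelResult(fit, {})
    summaries = {}
    for nm in ("intercept", "group", "block_type", "group_x_block"):
        summaries[nm] = PosteriorSummary.from_draws(nm, fit.draws[nm],
                                                    scale="log-ms")
    for nm in ("block_effect_ms", "group_effect_ms", "interaction_ms"):
        summaries[nm] = PosteriorSummary.from_draws(nm, fit.draws[nm],
                                                    scale="ms")
    return ModelResult(fit, summaries)


def _ce_per_participant(trials: pd.DataFrame) -> pd.DataFrame:
    nogo = trials[trials["trial_type"] == "NoGo"]
    if nogo.empty:
        raise ValueError("no NoGo trials: cannot model commission errors")
    ce = (nogo.groupby(["participant_id", "group"])["responded"]
          .agg(count="sum", exposure="size").reset_index())
    ce["count"] = ce["count"].astype(float)
    return ce


def fit_ce_model(trials: pd.DataFrame, n_draws: int = 2000,
                 seed: int = 0) -> ModelResult:
    """Poisson commission-error model with participant random intercept.

    Counts are modelled with a log-exposure offset (NoGo trials seen per
    participant); the group effect is reported on the model (log-rate)
    scale, on the count scale per 80 NoGo trials (Control minus
    Synchronized: positive = Control makes more errors), and as an
    error-rate percentage (count / 80 x 100).
    """
    trials = parse_trials(trials)
    ce = _ce_per_participant(trials)
    g = (ce["group"] == "Synchronized").to_numpy(float)
    X = np.column_stack([np.ones(len(ce)), g])
    fit = fit_poisson(ce["count"].to_numpy(), X,
                      offset=np.log(ce["exposure"].to_numpy()),
                      random_intercept=True, n_draws=n_draws, seed=seed,
                      coef_names=("intercept", "group"))
    b = fit.draws["beta"]
    tau2 = fit.draws["tau"] ** 2
    mean_c = FULL_TASK_NOGO * np.exp(b[:, 0] + 0.5 * tau2)
    mean_s = FULL_TASK_NOGO * np.exp(b[:, 0] + b[:, 1] + 0.5 * tau2)
    diff = mean_c - mean_s
    fit.draws["group_effect_count"] = diff
    fit.draws["group_effect_rate_pct"] = diff / FULL_TASK_NOGO * 100.0
    fit.draws["mean_count[Control]"] = mean_c
    fit.draws["mean_count[Synchronized]"] = mean_s
    if _withheld(fit):
        return ModelResult(fit, {})
    summaries = {
        "intercept": PosteriorSummary.from_draws(
            "intercept", b[:, 0], scale="log-rate"),
        "group": PosteriorSummary.from_draws("group", b[:, 1],
                                             scale="log-rate"),
        "group_effect_count": PosteriorSummary.from_draws(
            "group_effect_count", diff, scale="errors-per-80-NoGo"),
        "group_effect_rate_pct": PosteriorSummary.from_draws(
            "group_effect_rate_pct", fit.draws["group_effect_rate_pct"],
            scale="percent"),
    }
    return ModelResult(fit, summaries)


def fit_rt_ce_model(trials: pd.DataFrame, n_draws: int = 2000,
                    seed: int = 0) -> ModelResult:
    """Exploratory Poisson model of commission errors on mean reaction time.

    One observation per participant: commission-error count with
    log-exposure offset regressed on the participant's mean Go-trial RT
    (ms, centred).  The slope is reported in log-count per ms.  With one
    count per participant an additional random intercept is not separable
    from the Poisson variation, so the model has fixed effects only.
    """
    trials = parse_trials(trials)
    ce = _ce_per_participant(trials)
    go = trials[(trials["trial_type"] == "Go") & trials["responded"]]
    mean_rt = go.groupby("participant_id")["rt_ms"].mean()
    ce = ce.join(mean_rt.rename("mean_rt"), on="participant_id")
    if ce["mean_rt"].isna().any():
        missing = ce.loc[ce["mean_rt"].isna(), "participant_id"].tolist()
        raise ValueError(f"no Go-trial RTs for participants: {missing}")
    rt_c = ce["mean_rt"].to_numpy() - ce["mean_rt"].mean()
    X = np.column_stack([np.ones(len(ce)), rt_c])
    fit = fit_poisson(ce["count"].to_numpy(), X,
                      offset=np.log(ce["exposure"].to_numpy()),
                      random_intercept=False, n_draws=n_draws, seed=seed,
                      coef_names=("intercept", "rt_slope"))
    if _withheld(fit):
        return ModelResult(fit, {})
    summaries = {
        "rt_slope": PosteriorSummary.from_draws(
            "rt_slope", fit.draws["rt_slope"], scale="log-count-per-ms"),
        "intercept": PosteriorSummary.from_draws(
            "intercept", fit.draws["intercept"], scale="log-rate"),
    }
    return ModelResult(fit, summaries)
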