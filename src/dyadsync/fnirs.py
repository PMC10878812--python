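"""First-level fNIRS analysis: raw intensity to per-ROI evoked amplitudes.

Implements the continuous-wave fNIRS processing chain for a Go/NoGo block
design: downsampling (4.5 -> 0.6 Hz), conversion of raw two-wavelength
intensity to optical density and then to HbO/HbR concentration changes via
the modified Beer-Lambert law (partial pathlength factor 0.1 combining
DPF and partial-volume correction), and a per-channel GLM with

* one regressor per block type (16-s boxcar at block onsets convolved
  with a canonical double-gamma haemodynamic response function),
* a discrete-cosine drift basis spanning frequencies up to 0.01 Hz,
* all principal components of the short (8 mm) channels per chromophore
  as systemic nuisance regressors, and
* a lag-1 autoregressive noise model (Cochrane-Orcutt prewhitening).

Channel estimates are restricted to 20-40 mm source-detector separations
and pooled per region of interest by inverse-variance weighting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.stats import gamma as _gamma_dist
import statsmodels.api as sm

__all__ = [
    "WAVELENGTHS",
    "EXTINCTION_BASE10",
    "PPF",
    "Montage",
    "default_montage",
    "study_montage",
    "RawIntensity",
    "ODSeries",
    "HaemoSeries",
    "save_raw",
    "load_raw",
    "canonical_hrf",
    "task_regressor",
    "downsample",
    "intensity_to_od",
    "od_to_haemoglobin",
    "build_design_matrix",
    "fit_glm_ar1",
    "select_long_channels",
    "roi_average",
    "first_level",
]

ROIS = ("LIFG", "LPFC", "MPFC", "RPFC", "RIFG")
WAVELENGTHS = (760, 850)  # nm

#: Decadic molar extinction coefficients [1/(cm * M)] for HbO2 and HbR at
#: the instrument wavelengths, from the standard Gratzer/Kollias
#: compilation distributed with the common fNIRS toolboxes.
EXTINCTION_BASE10 = {
    760: {"hbo": 586.0, "hbr": 1548.52},
    850: {"hbo": 1058.0, "hbr": 691.32},
}
_LN10 = np.log(10.0)

#: Combined partial pathlength factor: differential pathlength factor 6
#: divided by partial volume correction 60.
PPF = 0.1

#: Boxcar duration (s) of the block regressor.
BOXCAR_S = 16.0
#: Drift cutoff: cosine regressors cover frequencies up to this (Hz).
DRIFT_CUTOFF_HZ = 0.01
#: Anti-alias low-pass corner (Hz) used before decimation to 0.6 Hz;
#: sits below the target Nyquist (0.3 Hz) to keep Mayer-wave energy from
#: aliasing.
_ANTIALIAS_HZ = 0.24


# --------------------------------------------------------------------------
# Montage
# --------------------------------------------------------------------------

@dataclass
class Montage:
    """Channel table: name, source, detector, separation (mm), ROI, short flag.

    Long channels (~30 mm) each map to exactly one ROI; short channels
    (8 mm) sample the scalp/systemic signal and carry no ROI.
    """

    channels: pd.DataFrame

    def __post_init__(self):
        required = {"name", "source", "detector", "separation_mm", "roi",
                    "is_short"}
        missing = required - set(self.channels.columns)
        if missing:
            raise ValueError(f"montage table missing columns: {sorted(missing)}")
        long_ch = self.channels[~self.channels["is_short"]]
        if long_ch["roi"].isna().any():
            raise ValueError("every long channel must map to a ROI")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def long_names(self):
        return list(self.channels.loc[~self.channels["is_short"], "name"])

    @property
    def short_names(self):
        return list(self.channels.loc[self.channels["is_short"], "name"])

    def roi_of(self, name: str):
        row = self.channels.loc[self.channels["name"] == name]
        return None if row.empty else row["roi"].iloc[0]


def _build_montage(long_per_roi: int, n_short: int,
                   long_sep_mm=30.0, short_sep_mm=8.0) -> Montage:
    rows = []
    src = 1
    det = 1
    for roi in ROIS:
        for k in range(long_per_roi):
            rows.append(dict(name=f"{roi}_ch{k + 1}", source=f"S{src}",
                             detector=f"D{det}", separation_mm=long_sep_mm,
                             roi=roi, is_short=False))
            det += 1
            if (len(rows)) % 3 == 0:
                src += 1
    for k in range(n_short):
        rows.append(dict(name=f"SC{k + 1}", source=f"S{k % src + 1}",
                         detector=f"SD{k + 1}", separation_mm=short_sep_mm,
                         roi=None, is_short=True))
    return Montage(pd.DataFrame(rows))


def default_montage(long_per_roi: int = 2, n_short: int = 4) -> Montage:
    """Compact montage used by the synthetic pipeline and tests."""
    return _build_montage(long_per_roi, n_short)


def study_montage() -> Montage:
    """Full-size montage: 38 long (30 mm) + 8 short (8 mm) channels over
    bilateral IFG and left/middle/right PFC (LIFG and RIFG carry 7 long
    channels, the PFC regions 8)."""
    m1 = _build_montage(8, 8)
    ch = m1.channels
    drop = ch["name"].isin(["LIFG_ch8", "RIFG_ch8"])
    return Montage(ch[~drop].reset_index(drop=True))


# --------------------------------------------------------------------------
# Containers
# --------------------------------------------------------------------------

@dataclass
class RawIntensity:
    """Two-wavelength raw intensity recording.

    ``intensity`` has shape (n_channels, 2, n_samples); axis 1 follows
    :data:`WAVELENGTHS`.  ``events`` is a table with columns
    onset_s, duration_s, condition.
    """

    intensity: np.ndarray
    montage: Montage
    fs: float
    events: pd.DataFrame

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3 or self.intensity.shape[1] != 2:
            raise ValueError("intensity must have shape (n_channels, 2, n_samples)")
        if self.intensity.shape[0] != self.montage.n_channels:
            raise ValueError("intensity rows must match montage channels")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class ODSeries:
    """Optical-density change per channel x wavelength (natural log)."""

    od: np.ndarray
    montage: Montage
    fs: float
    events: pd.DataFrame


@dataclass
class HaemoSeries:
    """HbO/HbR concentration change (uM) per channel."""

    hbo: np.ndarray
    hbr: np.ndarray
    montage: Montage
    fs: float
    events: pd.DataFrame

    def __post_init__(self):
        self.hbo = np.asarray(self.hbo, dtype=float)
        self.hbr = np.asarray(self.hbr, dtype=float)
        if self.hbo.shape != self.hbr.shape:
            raise ValueError("hbo and hbr must be paired per channel")
        if not (np.isfinite(self.hbo).all() and np.isfinite(self.hbr).all()):
            raise ValueError("concentrations must be finite")

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[1]

    def select(self, names):
        idx = [list(self.montage.channels["name"]).index(n) for n in names]
        sub = Montage(self.montage.channels.iloc[idx].reset_index(drop=True))
        return HaemoSeries(self.hbo[idx], self.hbr[idx], sub, self.fs,
                           self.events)


# --------------------------------------------------------------------------
# Raw-recording container I/O (CSV + geometry sidecar + events TSV)
# --------------------------------------------------------------------------

def save_raw(raw: RawIntensity, prefix) -> None:
    """Write a recording as three text files sharing a path prefix.

    ``<prefix>_intensity.csv``: wide table, one column per
    channel/wavelength (``name@760``, ``name@850``) plus ``time_s``;
    ``<prefix>_montage.json``: the channel geometry sidecar;
    ``<prefix>_events.tsv``: onset_s, duration_s, condition.
    """
    import json
    from pathlib import Path

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    t = np.arange(raw.n_samples) / raw.fs
    cols = {"time_s": t}
    for c, name in enumerate(raw.montage.channels["name"]):
        for w, wl in enumerate(WAVELENGTHS):
            cols[f"{name}@{wl}"] = raw.intensity[c, w]
    pd.DataFrame(cols).to_csv(f"{prefix}_intensity.csv", index=False,
                              float_format="%.10g")
    side = dict(sampling_rate_hz=raw.fs,
                channels=raw.montage.channels.where(
                    raw.montage.channels.notna(), None)
                .to_dict(orient="records"))
    Path(f"{prefix}_montage.json").write_text(json.dumps(side, indent=2))
    raw.events.to_csv(f"{prefix}_events.tsv", sep="\t", index=False)


def load_raw(prefix) -> RawIntensity:
    """Read a recording written by :func:`save_raw`."""
    import json

    with open(f"{prefix}_montage.json") as fh:
        side = json.load(fh)
    montage = Montage(pd.DataFrame(side["channels"]))
    inten_df = pd.read_csv(f"{prefix}_intensity.csv")
    n = len(inten_df)
    data = np.empty((montage.n_channels, 2, n))
    for c, name in enumerate(montage.channels["name"]):
        for w, wl in enumerate(WAVELENGTHS):
            data[c, w] = inten_df[f"{name}@{wl}"].to_numpy()
    events = pd.read_csv(f"{prefix}_events.tsv", sep="\t")
    return RawIntensity(data, montage, float(side["sampling_rate_hz"]),
                        events)


# --------------------------------------------------------------------------
# HRF and task regressors
# --------------------------------------------------------------------------

def canonical_hrf(dt: float, duration: float = 33.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled every ``dt`` seconds.

    Peak at 6 s, undershoot at 16 s, undershoot ratio 1/6; peak height 1.
    """
    t = np.arange(0.0, duration, dt)
    # gamma modes sit at (shape-1)*scale: shapes 7 and 17 with scale 1
    h = _gamma_dist.pdf(t, 7.0) - _gamma_dist.pdf(t, 17.0) / 6.0
    return h / h.max()


def task_regressor(onsets_s, n_samples: int, fs: float,
                   boxcar_s: float = BOXCAR_S) -> np.ndarray:
    """Block regressor: 16-s boxcars at onsets convolved with the HRF.

    Scaled so that the response to a single isolated block peaks at 1,
    making the GLM amplitude the peak evoked concentration change.
    """
    onsets_s = np.asarray(onsets_s, dtype=float)
    if (onsets_s < 0).any() or (onsets_s > n_samples / fs).any():
        raise ValueError("event onset beyond the recording")
    stick = np.zeros(n_samples)
    width = max(1, int(round(boxcar_s * fs)))
    for on in onsets_s:
        i = int(round(on * fs))
        stick[i: i + width] = 1.0
    h = canonical_hrf(1.0 / fs)
    conv = np.convolve(stick, h)[:n_samples]
    single = np.convolve(np.ones(width), h)
    return conv / single.max()


# --------------------------------------------------------------------------
# Preprocessing stages
# --------------------------------------------------------------------------

def downsample_series(x: np.ndarray, fs: float, target_hz: float) -> np.ndarray:
    """Zero-phase anti-alias low-pass then linear resampling of the last
    axis onto the ``target_hz`` grid."""
    if target_hz >= fs:
        raise ValueError("target rate must be below the source rate")
    x = np.asarray(x, dtype=float)
    sos = signal.butter(5, _ANTIALIAS_HZ, fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, x, axis=-1)
    n = x.shape[-1]
    t_old = np.arange(n) / fs
    t_new = np.arange(0.0, n / fs, 1.0 / target_hz)
    out = np.empty(x.shape[:-1] + (t_new.size,))
    for idx in np.ndindex(x.shape[:-1]):
        out[idx] = np.interp(t_new, t_old, filt[idx])
    return out


def downsample(raw: RawIntensity, target_hz: float = 0.6) -> RawIntensity:
    """Anti-alias low-pass then resample onto a ``target_hz`` grid.

    Zero-phase Butterworth filtering (corner below the target Nyquist)
    followed by sample selection on the new time grid; event onsets are
    in seconds and carry over unchanged.
    """
    out = downsample_series(raw.intensity, raw.fs, target_hz)
    return RawIntensity(out, raw.montage, target_hz, raw.events)


def intensity_to_od(raw: RawIntensity) -> ODSeries:
    """Optical density OD(t) = -ln(I(t) / mean(I)) per channel/wavelength."""
    bad = (raw.intensity <= 0).any(axis=(1, 2))
    if bad.any():
        names = [raw.montage.channels["name"].iloc[i]
                 for i in np.nonzero(bad)[0]]
        raise ValueError(f"non-positive intensities in channels: {names}")
    mean = raw.intensity.mean(axis=-1, keepdims=True)
    od = -np.log(raw.intensity / mean)
    return ODSeries(od, raw.montage, raw.fs, raw.events)


def _extinction_matrix() -> np.ndarray:
    """Rows: wavelengths (760, 850); columns: (HbO, HbR); decadic, cm^-1/M."""
    return np.array([[EXTINCTION_BASE10[wl]["hbo"],
                      EXTINCTION_BASE10[wl]["hbr"]] for wl in WAVELENGTHS])


def od_to_haemoglobin(od: ODSeries, ppf: float = PPF) -> HaemoSeries:
    """Modified Beer-Lambert inversion to HbO/HbR concentration change (uM).

    Per sample and channel, solves the 2 x 2 system
    ``OD_lambda = ln(10) * (eps_HbO * dHbO + eps_HbR * dHbR) * d * ppf``
    with d the source-detector separation in cm; the natural-log OD is
    divided by ln(10) to match the decadic extinction coefficients.
    """
    E = _extinction_matrix()
    Einv = np.linalg.inv(E)
    sep_cm = od.montage.channels["separation_mm"].to_numpy() / 10.0
    scale = 1.0 / (_LN10 * sep_cm * ppf)  # per channel
    # (2,2) @ (n_ch, 2, n_s) over wavelength axis
    conc_molar = np.einsum("kw,cws->cks", Einv, od.od) * scale[:, None, None]
    conc_um = conc_molar * 1e6
    return HaemoSeries(conc_um[:, 0, :], conc_um[:, 1, :], od.montage,
                       od.fs, od.events)


def haemoglobin_to_intensity(haemo: HaemoSeries, baseline, ppf: float = PPF
                             ) -> RawIntensity:
    """Forward Beer-Lambert step: concentrations (uM) to raw intensity.

    The exact inverse of :func:`intensity_to_od` followed by
    :func:`od_to_haemoglobin` up to the per-channel baseline intensity
    (``baseline``, shape (n_channels, 2) or scalar).
    """
    E = _extinction_matrix()
    sep_cm = haemo.montage.channels["separation_mm"].to_numpy() / 10.0
    conc = np.stack([haemo.hbo, haemo.hbr], axis=1) * 1e-6
    od = np.einsum("wk,cks->cws", E, conc) * (
        _LN10 * sep_cm[:, None, None] * ppf)
    base = np.broadcast_to(np.asarray(baseline, dtype=float).reshape(-1, 2)
                           if np.ndim(baseline) else
                           np.full((1, 2), baseline),
                           (haemo.hbo.shape[0], 2))
    inten = base[:, :, None] * np.exp(-od)
    return RawIntensity(inten, haemo.montage, haemo.fs, haemo.events)


# --------------------------------------------------------------------------
# Design matrix and GLM
# --------------------------------------------------------------------------

def _dct_drift(n_samples: int, fs: float,
               cutoff_hz: float = DRIFT_CUTOFF_HZ) -> np.ndarray:
    """DCT-II basis columns with frequency <= cutoff (constant excluded)."""
    duration = n_samples / fs
    k_max = int(np.floor(2.0 * duration * cutoff_hz))
    t = np.arange(n_samples)
    cols = [np.cos(np.pi * k * (2 * t + 1) / (2 * n_samples))
            for k in range(1, k_max + 1)]
    if not cols:
        return np.empty((n_samples, 0))
    return np.column_stack(cols)


def build_design_matrix(events: pd.DataFrame, n_samples: int, fs: float,
                        short: np.ndarray | None = None,
                        drift_cutoff_hz: float = DRIFT_CUTOFF_HZ,
                        task_columns: dict | None = None
                        ) -> pd.DataFrame:
    """Assemble the first-level design for one chromophore.

    Columns: one HRF-convolved boxcar regressor per condition (sorted
    condition names), cosine drift terms up to ``drift_cutoff_hz``, all
    principal components of the ``short`` channel array (n_short x
    n_samples, already converted to the same chromophore), and a constant.
    ``task_columns`` overrides the constructed task regressors (used when
    the data were resampled, so regressors can be passed through the same
    resampling as the data).
    """
    cols = {}
    if task_columns is not None:
        for cond in sorted(task_columns):
            cols[cond] = np.asarray(task_columns[cond], dtype=float)
    elif events is not None and len(events):
        for cond in sorted(events["condition"].unique()):
            on = events.loc[events["condition"] == cond, "onset_s"]
            cols[cond] = task_regressor(on.to_numpy(), n_samples, fs)
    drift = _dct_drift(n_samples, fs, drift_cutoff_hz)
    for k in range(drift.shape[1]):
        cols[f"drift_{k + 1}"] = drift[:, k]
    if short is not None and len(short):
        S = np.asarray(short, dtype=float)
        S = S - S.mean(axis=1, keepdims=True)
        # all principal components of the short-channel series
        U, sv, _ = np.linalg.svd(S.T, full_matrices=False)
        keep = sv > 1e-10 * max(sv.max(), 1.0)
        pcs = U[:, keep]
        for k in range(pcs.shape[1]):
            cols[f"short_pc_{k + 1}"] = pcs[:, k]
    cols["const"] = np.ones(n_samples)
    return pd.DataFrame(cols)


def _ar1_fit(y: np.ndarray, X: np.ndarray, iterations: int = 1):
    """Cochrane-Orcutt AR(1) GLM via statsmodels GLSAR.

    One pass by default: OLS -> rho from lag-1 residual autocorrelation ->
    prewhiten -> refit.  Returns (params, bse, rho).
    """
    model = sm.GLSAR(y, X, rho=1)
    res = model.iterative_fit(maxiter=iterations + 1)
    return res.params, res.bse, float(np.atleast_1d(model.rho)[0])


def fit_glm_ar1(haemo: HaemoSeries, short_haemo: HaemoSeries | None = None,
                drift_cutoff_hz: float = DRIFT_CUTOFF_HZ,
                ar_iterations: int = 1,
                task_columns: dict | None = None) -> pd.DataFrame:
    """Per-channel, per-chromophore AR(1) GLM amplitude estimates.

    Returns a tidy table: channel, roi, separation_mm, chromophore,
    condition, beta (uM), se (uM), rho.
    """
    conditions = sorted(haemo.events["condition"].unique())
    out = []
    for chrom in ("hbo", "hbr"):
        short = None
        if short_haemo is not None:
            short = getattr(short_haemo, chrom)
        design = build_design_matrix(haemo.events, haemo.n_samples, haemo.fs,
                                     short=short,
                                     drift_cutoff_hz=drift_cutoff_hz,
                                     task_columns=task_columns)
        X = design.to_numpy()
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise ValueError(
                "design matrix is rank deficient; check drift/PC columns "
                f"(rank {rank} < {X.shape[1]})")
        data = getattr(haemo, chrom)
        for c, name in enumerate(haemo.montage.channels["name"]):
            params, bse, rho = _ar1_fit(data[c], X, iterations=ar_iterations)
            row_meta = haemo.montage.channels.iloc[c]
            for cond in conditions:
                j = list(design.columns).index(cond)
                out.append(dict(channel=name, roi=row_meta["roi"],
                                separation_mm=row_meta["separation_mm"],
                                chromophore=chrom, condition=cond,
                                beta=params[j], se=bse[j], rho=rho))
    return pd.DataFrame(out)


def select_long_channels(betas: pd.DataFrame, min_mm: float = 20.0,
                         max_mm: float = 40.0) -> pd.DataFrame:
    """Keep channels with source-detector separation in [20, 40] mm."""
    keep = (betas["separation_mm"] >= min_mm) & (betas["separation_mm"] <= max_mm)
    return betas[keep].reset_index(drop=True)


def roi_average(betas: pd.DataFrame) -> pd.DataFrame:
    """Inverse-variance pooling of channel betas per (ROI, condition,
    chromophore): pooled beta = sum(w b)/sum(w), w = 1/se^2; pooled
    se = sum(w)^(-1/2).  ROIs with no channels are absent from the output
    (flagged missing by callers), never zero-filled."""
    rows = []
    grouped = betas.dropna(subset=["roi"]).groupby(
        ["roi", "condition", "chromophore"], sort=True)
    for (roi, cond, chrom), g in grouped:
        w = 1.0 / g["se"].to_numpy() ** 2
        b = g["beta"].to_numpy()
        rows.append(dict(roi=roi, condition=cond, chromophore=chrom,
                         beta=float((w * b).sum() / w.sum()),
                         se=float(w.sum() ** -0.5),
                         n_channels=len(g)))
    return pd.DataFrame(rows)


def first_level(raw: RawIntensity, target_hz: float | None = 0.6,
                ppf: float = PPF, ar_iterations: int = 1,
                use_short_regression: bool = True):
    """Run the full first-level chain on one participant's recording.

    Returns ``(channel_betas, roi_estimates)``.  Set ``target_hz=None``
    to skip downsampling (useful for exact noise-free checks).  When
    downsampling, the task regressors are built at the acquisition rate
    and passed through the same anti-alias resampling as the data, so
    the regressor shape stays consistent with the filtered signal.
    """
    task_columns = None
    if target_hz is not None:
        task_columns = {}
        for cond in sorted(raw.events["condition"].unique()):
            on = raw.events.loc[raw.events["condition"] == cond, "onset_s"]
            reg = task_regressor(on.to_numpy(), raw.n_samples, raw.fs)
            task_columns[cond] = downsample_series(reg, raw.fs, target_hz)
        raw = downsample(raw, target_hz)
    haemo = od_to_haemoglobin(intensity_to_od(raw), ppf=ppf)
    long_h = haemo.select(raw.montage.long_names)
    short_h = None
    if use_short_regression and raw.montage.short_names:
        short_h = haemo.select(raw.montage.short_names)
    betas = fit_glm_ar1(long_h, short_h, ar_iterations=ar_iterations,
                        task_columns=task_columns)
    betas = select_long_channels(betas)
    return betas, roi_average(betas)
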