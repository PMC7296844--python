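"""Event-related GLM tools: canonical HRF, design matrices, OLS, group
correlations, Monte-Carlo cluster-extent thresholds, conjunctions and ROI
principal-component extraction.

Event trains are built as truncated delta functions at a microtime
resolution of 16 bins per TR, convolved with the canonical double-gamma
hemodynamic response (peak delay 6 s, undershoot delay 16 s, unit
dispersions, undershoot ratio 6, 32 s support) and downsampled to the scan
grid. Two design variants mirror the analysis: a categorical variant with
four outcome columns (reward/no-reward x choice/no-choice) and a modulated
variant replacing them with one outcome column plus a mean-centred
parametric modulator (binary reward or the model-derived RPE).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .behavior import spearman
from .task import CHOICE, TaskConfig

MICRO_PER_TR = 16

HRF_PEAK_DELAY = 6.0
HRF_UNDERSHOOT_DELAY = 16.0
HRF_PEAK_DISP = 1.0
HRF_UNDERSHOOT_DISP = 1.0
HRF_RATIO = 6.0
HRF_LENGTH = 32.0


def hrf_kernel(dt: float) -> np.ndarray:
    """Canonical double-gamma HRF sampled at resolution ``dt`` seconds."""
    t = np.arange(0, HRF_LENGTH + dt, dt)
    h = stats.gamma.pdf(t, HRF_PEAK_DELAY / HRF_PEAK_DISP, scale=HRF_PEAK_DISP) - stats.gamma.pdf(
        t, HRF_UNDERSHOOT_DELAY / HRF_UNDERSHOOT_DISP, scale=HRF_UNDERSHOOT_DISP
    ) / HRF_RATIO
    return h / h.sum()


@dataclass(frozen=True)
class DesignSpec:
    tr: float = 1.56
    n_scans: int = 500
    micro_per_tr: int = MICRO_PER_TR

    @property
    def dt(self) -> float:
        return self.tr / self.micro_per_tr


def _delta_train(onsets, durations, spec: DesignSpec) -> np.ndarray:
    n_micro = spec.n_scans * spec.micro_per_tr
    u = np.zeros(n_micro)
    for onset, dur in zip(np.atleast_1d(onsets), np.atleast_1d(durations)):
        i0 = int(round(onset / spec.dt))
        if i0 >= n_micro or onset < 0:
            raise ValueError(f"event at {onset:.2f}s lies outside the scan window")
        i1 = max(i0 + 1, int(round((onset + dur) / spec.dt)))
        u[i0 : min(i1, n_micro)] = 1.0
    return u


def _convolve_downsample(u: np.ndarray, spec: DesignSpec) -> np.ndarray:
    h = hrf_kernel(spec.dt)
    x = np.convolve(u, h)[: u.size]
    return x[:: spec.micro_per_tr]


def build_design(
    events: pd.DataFrame,
    variant: str = "categorical",
    modulator_values: np.ndarray | None = None,
    motion: np.ndarray | None = None,
    spec: DesignSpec | None = None,
) -> pd.DataFrame:
    """First-level design matrix for one subject.

    ``events`` needs columns onset, duration, trial_type, condition, outcome,
    missed (the events.tsv dialect written by :mod:`rewardconn.io`). The
    categorical variant has 4 outcome columns; the modulated variant one
    outcome column plus a parametric modulator (mean-centred before
    convolution) aligned to the non-missed outcome events in onset order.
    Motion covariates (n_scans x 6) are appended unconvolved, plus a constant.
    """
    spec = spec or DesignSpec()
    if variant not in ("categorical", "modulated"):
        raise ValueError("variant must be 'categorical' or 'modulated'")
    ev = events
    cols: dict[str, np.ndarray] = {}

    def series(mask, name):
        sel = ev[mask]
        if len(sel) == 0:
            cols[name] = np.zeros(spec.n_scans)
            return
        u = _delta_train(sel["onset"].to_numpy(), sel["duration"].to_numpy(), spec)
        cols[name] = _convolve_downsample(u, spec)

    is_cue = ev["trial_type"].str.startswith("cue")
    is_outcome = ev["trial_type"].str.startswith("outcome")
    is_resp = ev["trial_type"] == "response"
    is_choice = ev["condition"] == CHOICE

    series(is_cue & is_choice, "cue_choice")
    series(is_cue & ~is_choice, "cue_nochoice")
    if variant == "categorical":
        win = ev["trial_type"] == "outcome_win"
        series(is_outcome & win & is_choice, "outcome_win_choice")
        series(is_outcome & ~win & is_choice, "outcome_nowin_choice")
        series(is_outcome & win & ~is_choice, "outcome_win_nochoice")
        series(is_outcome & ~win & ~is_choice, "outcome_nowin_nochoice")
    else:
        series(is_outcome, "outcome_all")
        out_ev = ev[is_outcome].sort_values("onset")
        if modulator_values is None:
            raise ValueError("modulated variant needs modulator_values")
        m = np.asarray(modulator_values, dtype=float)
        if m.size != len(out_ev):
            raise ValueError("modulator_values must align with the outcome events")
        m = m - m.mean()
        u = np.zeros(spec.n_scans * spec.micro_per_tr)
        for val, (_, row) in zip(m, out_ev.iterrows()):
            tr_u = _delta_train([row["onset"]], [row["duration"]], spec)
            u += val * tr_u
        cols["outcome_modulator"] = _convolve_downsample(u, spec)
    series(is_resp & is_choice, "response_choice")
    series(is_resp & ~is_choice, "response_nochoice")
    # nuisance column: missed / invalid trials
    missed = ev["missed"].astype(bool) & is_cue
    series(missed, "nuisance")

    X = pd.DataFrame(cols)
    # event types with no occurrences (e.g. no missed trials) would yield
    # all-zero regressors and a rank-deficient design; omit them
    X = X.loc[:, (X != 0).any(axis=0)]
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape != (spec.n_scans, 6):
            raise ValueError("motion must be (n_scans, 6)")
        for k in range(6):
            X[f"motion_{k + 1}"] = motion[:, k]
    X["constant"] = 1.0
    return X


def fit_first_level(Y: np.ndarray, X: pd.DataFrame | np.ndarray):
    """OLS fit; returns (betas, residual variance).

    ``Y`` may be (n_scans,) or (n_scans, n_series). Raises on rank-deficient
    designs, naming the collinear columns when ``X`` is a DataFrame.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    Xm = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    n, p = Xm.shape
    rank = np.linalg.matrix_rank(Xm)
    if rank < p:
        if names is not None:
            # identify columns whose removal restores full rank
            bad = [
                names[j]
                for j in range(p)
                if np.linalg.matrix_rank(np.delete(Xm, j, axis=1)) == rank
            ]
            raise np.linalg.LinAlgError(f"design is rank deficient; collinear columns: {bad}")
        raise np.linalg.LinAlgError("design is rank deficient")
    Y = np.asarray(Y, dtype=float)
    beta, _, _, _ = np.linalg.lstsq(Xm, Y, rcond=None)
    resid = Y - Xm @ beta
    dof = max(n - p, 1)
    resid_var = np.sum(resid**2, axis=0) / dof
    return beta, resid_var


def contrast_estimate(beta: np.ndarray, c: np.ndarray) -> float | np.ndarray:
    """Contrast of parameter estimates c' beta."""
    return np.asarray(c, dtype=float) @ beta


def second_level_correlation(contrast_values: np.ndarray, scores: np.ndarray):
    """Across-subject Spearman correlation of first-level contrasts with a score.

    ``contrast_values`` is (n_subjects,) or (n_subjects, n_units); returns
    (rho, p) per unit, scalars in the single-unit case.
    """
    cv = np.asarray(contrast_values, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if cv.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if cv.ndim == 1:
        return spearman(cv, scores)
    out = np.array([spearman(cv[:, k], scores) for k in range(cv.shape[1])])
    return out[:, 0], out[:, 1]


def _smooth_and_standardize(field: np.ndarray, sigma_vox: np.ndarray) -> np.ndarray:
    """Gaussian smoothing with truncated (wrap-free) edges, rescaled so every
    voxel is again unit variance under white-noise input."""
    if np.all(sigma_vox <= 0):
        return field
    sm = ndimage.gaussian_filter(field, sigma=sigma_vox, mode="constant")
    # per-voxel variance of the truncated kernel: convolve ones with w^2
    var = np.ones_like(field)
    for ax, s in enumerate(sigma_vox):
        if s <= 0:
            continue
        radius = int(4.0 * s + 0.5)
        xs = np.arange(-radius, radius + 1)
        w = np.exp(-0.5 * (xs / s) ** 2)
        w = w / w.sum()
        var = ndimage.convolve1d(var, w**2, axis=ax, mode="constant")
    return sm / np.sqrt(var)


def mc_cluster_threshold(
    grid_shape: tuple[int, int, int],
    voxel_size: float,
    fwhm: float,
    voxel_p: float = 0.05,
    fwe_p: float = 0.001,
    n_sims: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> int:
    """Cluster-extent threshold by Monte-Carlo simulation of smooth noise.

    White Gaussian fields on ``grid_shape`` are smoothed to the target FWHM
    (sigma = FWHM / 2.355 per axis, truncated edges with variance
    renormalization), thresholded two-sided at ``voxel_p``, and the largest
    26-connected supra-threshold cluster recorded per simulation. The
    returned extent is the ceiling of the (1 - fwe_p) quantile of that
    null distribution.
    """
    if fwhm < voxel_size:
        raise ValueError("fwhm must be at least one voxel")
    if n_sims < 100:
        import warnings

        warnings.warn("fewer than 100 simulations gives an unstable extent estimate")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma_vox = np.full(3, (fwhm / voxel_size) / 2.355)
    if fwhm == voxel_size:
        sigma_vox[:] = 0.0  # no smoothing
    zthr = stats.norm.ppf(1.0 - voxel_p / 2.0)
    structure = np.ones((3, 3, 3), dtype=int)  # 26-neighbour connectivity
    max_sizes = np.zeros(n_sims)
    for s in range(n_sims):
        field = rng.standard_normal(grid_shape)
        z = _smooth_and_standardize(field, sigma_vox)
        supra = np.abs(z) > zthr
        labels, n = ndimage.label(supra, structure=structure)
        if n:
            sizes = np.bincount(labels.ravel())[1:]
            max_sizes[s] = sizes.max()
    return int(np.ceil(np.quantile(max_sizes, 1.0 - fwe_p)))


def conjunction(mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Sign-consistent voxelwise AND of two (possibly signed) masks."""
    a = np.asarray(mask_a)
    b = np.asarray(mask_b)
    if a.shape != b.shape:
        raise ValueError("masks must have the same shape")
    sa = np.sign(a).astype(int)
    sb = np.sign(b).astype(int)
    return np.where(sa == sb, sa, 0) * (sa != 0)


def roi_first_pc(voxel_block: np.ndarray) -> np.ndarray:
    """First principal component over voxels of a (voxels x time) block.

    Sign-aligned so the mean voxel loading is positive, scaled to unit
    variance over time.
    """
    B = np.asarray(voxel_block, dtype=float)
    if B.ndim != 2 or B.shape[0] < 2:
        raise ValueError("need a (voxels x time) block with >= 2 voxels")
    Bc = B - B.mean(axis=1, keepdims=True)
    if np.allclose(Bc, 0):
        raise ValueError("constant voxel block has no principal component")
    U, s, Vt = np.linalg.svd(Bc, full_matrices=False)
    pc = Vt[0]
    if U[:, 0].mean() < 0:
        pc = -pc
    sd = pc.std()
    return pc / sd if sd > 0 else pc
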