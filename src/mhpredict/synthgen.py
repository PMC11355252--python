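"""Synthetic cohorts and macular-hole annotation masks.

The study cohort (43 eyes: 32 with good and 11 with poor 6-month visual
outcome) is not publicly available, so this module generates stand-ins with
the statistical and geometric structure the downstream analysis assumes:

* :func:`sample_feature_table` draws group-conditional cohorts whose base
  continuous features reproduce the published per-group means and SDs, with
  within-group correlations recovered from the printed SDs of the difference
  features via Var(X-Y) = Var(X) + Var(Y) - 2 rho sx sy, and categorical
  features drawn from the published per-group counts.  All sixteen
  combination features are computed deterministically from the sampled base
  features, never sampled independently.

* :func:`render_synthetic_mask` rasterises a parametric macular-hole
  annotation mask (flood-filled retinal bands interrupted by a central
  funnel-shaped cavity) and returns the exact ground-truth morphometry
  implied by the rasterised geometry, so feature extraction can be verified
  by round trip.

Nonnegative features (lengths and areas) use truncated-normal marginals whose
underlying parameters are moment-matched so the *truncated* distribution has
exactly the configured mean and SD; the joint is a Gaussian copula over the
configured correlation matrix (repaired to the nearest positive-semidefinite
matrix when necessary, with the adjustment logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from . import octfeat
from .octfeat import (
    CATEGORICAL_LEVELS,
    DEFAULT_PITCH_UM,
    DIFFERENCE_FEATURES,
    FEATURE_NAMES,
    GROUP_GOOD,
    GROUP_POOR,
    LABEL_COLUMN,
    LayerMask,
    MORPHOMETRIC_BASE,
    ONL_SDL,
    RATIO_FEATURES,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GeneratorConfig",
    "MaskGeometry",
    "InfeasibleVarianceError",
    "derive_within_group_correlation",
    "default_generator_config",
    "sample_feature_table",
    "render_synthetic_mask",
    "random_geometry",
    "DEFAULT_FEATURE_PARAMS",
    "DEFAULT_CATEGORICAL_PROBS",
    "DIFFERENCE_SD_TABLE",
]

# --------------------------------------------------------------------------
# Published per-group summary statistics (mean_a, sd_a, mean_b, sd_b)
# --------------------------------------------------------------------------

#: baseline per-group moments of the 18 base continuous features.
#: Units: BCVA in logMAR, axial length in mm, disease duration in months,
#: lengths in um, areas in px^2 of the 256x256 trim.
DEFAULT_FEATURE_PARAMS: dict[str, tuple[float, float, float, float]] = {
    "Age": (65.59, 6.51, 67.18, 4.63),
    "Preoperative BCVA": (0.46, 0.24, 0.81, 0.34),
    "Axial length": (23.98, 1.38, 24.05, 1.56),
    "Disease duration": (1.72, 2.05, 3.18, 3.46),
    "BDM": (724.66, 189.13, 958.45, 399.37),
    "Hole-min": (295.50, 107.49, 423.09, 175.49),
    "OPL-DL": (465.09, 140.14, 492.36, 170.95),
    ONL_SDL: (313.28, 115.73, 434.09, 186.22),
    "ELM-DL": (320.63, 120.25, 480.82, 221.77),
    "EZ-DL": (359.00, 172.47, 517.09, 263.87),
    "Green-sDL": (462.91, 134.37, 533.73, 148.32),
    "Sky blue-sDL": (297.13, 120.35, 458.27, 220.81),
    "Blue-sDL": (372.25, 168.61, 530.82, 256.59),
    "Area IRF": (1437.72, 910.70, 2240.36, 1653.83),
    "Area-green": (7268.78, 1414.01, 7122.45, 1195.36),
    "Area-yellow": (5263.59, 1220.27, 5068.27, 1463.88),
    "Area-sky_blue": (1585.31, 327.78, 1560.64, 215.41),
    "Area-blue": (1701.56, 417.81, 1744.73, 472.78),
}

BASE_CONTINUOUS: tuple[str, ...] = tuple(DEFAULT_FEATURE_PARAMS)

#: published per-group level counts of the categorical background items.
#: The invert / not-peel split of the non-peeled ILM eyes is not published;
#: the invert-heavy split below is a modelling choice (see docs/methods.md).
DEFAULT_CATEGORICAL_COUNTS: dict[str, tuple[dict[str, int], dict[str, int]]] = {
    "Sex": ({"Man": 10, "Woman": 22}, {"Man": 4, "Woman": 7}),
    "Method": ({"PPV": 1, "Phaco+PPV": 31}, {"PPV": 0, "Phaco+PPV": 11}),
    "Affected eye": ({"Right": 18, "Left": 14}, {"Right": 6, "Left": 5}),
    "Stage": ({"2": 3, "3": 24, "4": 5}, {"2": 3, "3": 7, "4": 1}),
    "ILM": ({"Peel": 22, "Invert": 8, "Not peel": 2}, {"Peel": 4, "Invert": 6, "Not peel": 1}),
    "VMT": ({"Present": 20, "Absent": 12}, {"Present": 6, "Absent": 5}),
    "PVD": ({"Complete": 27, "Not complete": 5}, {"Complete": 10, "Not complete": 1}),
}

DEFAULT_CATEGORICAL_PROBS: dict[str, tuple[dict[str, float], dict[str, float]]] = {
    name: tuple(
        {lvl: cnt / sum(group.values()) for lvl, cnt in group.items()} for group in groups
    )
    for name, groups in DEFAULT_CATEGORICAL_COUNTS.items()
}

#: printed SDs of the difference features, (pair, sd_diff_a, sd_diff_b);
#: each row pins the within-group correlation of its base-feature pair.
DIFFERENCE_SD_TABLE: tuple[tuple[tuple[str, str], float, float], ...] = (
    (("OPL-DL", ONL_SDL), 114.31, 46.37),
    (("ELM-DL", ONL_SDL), 42.69, 76.45),
    (("OPL-DL", "Green-sDL"), 95.99, 55.85),
    (("ELM-DL", "Sky blue-sDL"), 30.58, 22.67),
    (("EZ-DL", "Sky blue-sDL"), 82.83, 51.32),
    (("EZ-DL", "Blue-sDL"), 25.11, 22.21),
    (("BDM", "Blue-sDL"), 127.58, 231.34),
    (("BDM", "Hole-min"), 134.12, 250.01),
)


class InfeasibleVarianceError(ValueError):
    """The printed SD triple implies a correlation outside [-1, 1]."""


def derive_within_group_correlation(sd_x: float, sd_y: float, sd_diff: float) -> float:
    """Correlation of X and Y implied by SD(X), SD(Y) and SD(X - Y).

    From Var(X - Y) = Var(X) + Var(Y) - 2 rho sx sy:
    rho = (sx^2 + sy^2 - sd^2) / (2 sx sy).
    """
    if sd_x <= 0 or sd_y <= 0:
        raise ValueError("sd_x and sd_y must be positive")
    rho = (sd_x**2 + sd_y**2 - sd_diff**2) / (2.0 * sd_x * sd_y)
    if abs(rho) > 1.0 + 1e-9:
        raise InfeasibleVarianceError(
            f"implied correlation {rho:.4f} outside [-1, 1]: inconsistent SD triple"
        )
    return float(np.clip(rho, -1.0, 1.0))


# --------------------------------------------------------------------------
# Generator configuration
# --------------------------------------------------------------------------


@dataclass
class GeneratorConfig:
    """Cohort sampling configuration calibrated to the published summaries."""

    n_group_a: int = 32
    n_group_b: int = 11
    feature_params: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FEATURE_PARAMS)
    )
    #: pair -> correlation (applied to both groups) or (rho_a, rho_b)
    correlation_overrides: dict[tuple[str, str], object] = field(default_factory=dict)
    #: per-group correlations pinned by the published difference-feature SDs;
    #: recomputed from the default calibration, not from ``feature_params``
    pinned_correlations: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: derived_correlations(DEFAULT_FEATURE_PARAMS)
    )
    #: correlation for morphometric pairs not pinned by a difference-feature SD
    default_correlation: float = 0.5
    categorical_probs: dict[str, tuple[dict[str, float], dict[str, float]]] = field(
        default_factory=lambda: {
            k: (dict(a), dict(b)) for k, (a, b) in DEFAULT_CATEGORICAL_PROBS.items()
        }
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_group_a < 2 or self.n_group_b < 2:
            raise ValueError("each group needs at least 2 records")
        for name, (ma, sa, mb, sb) in self.feature_params.items():
            if sa < 0 or sb < 0:
                raise ValueError(f"negative SD configured for {name!r}")
        if not -1.0 <= self.default_correlation <= 1.0:
            raise ValueError("default_correlation must lie in [-1, 1]")
        for name, groups in self.categorical_probs.items():
            for probs in groups:
                total = sum(probs.values())
                if abs(total - 1.0) > 1e-8:
                    raise ValueError(f"probabilities for {name!r} sum to {total}, not 1")


def default_generator_config(seed: int = 0, **overrides) -> GeneratorConfig:
    return replace(GeneratorConfig(seed=seed), **overrides)


def derived_correlations(
    feature_params: dict[str, tuple[float, float, float, float]] | None = None,
) -> dict[tuple[str, str], tuple[float, float]]:
    """Per-group correlations pinned by the printed difference-feature SDs."""
    params = feature_params or DEFAULT_FEATURE_PARAMS
    out: dict[tuple[str, str], tuple[float, float]] = {}
    for (fx, fy), sd_a, sd_b in DIFFERENCE_SD_TABLE:
        _, sxa, _, sxb = params[fx]
        _, sya, _, syb = params[fy]
        out[(fx, fy)] = (
            derive_within_group_correlation(sxa, sya, sd_a),
            derive_within_group_correlation(sxb, syb, sd_b),
        )
    return out


_PSD_CACHE: dict[bytes, tuple[np.ndarray, float]] = {}


def nearest_positive_semidefinite(
    corr: np.ndarray, fixed: np.ndarray | None = None, tol: float = 1e-8,
    max_iter: int = 25_000,
) -> tuple[np.ndarray, float]:
    """Repair a correlation matrix to positive semidefiniteness.

    Alternating projections between the PSD cone (eigenvalue clipping) and
    the unit-diagonal constraint set.  Entries flagged in the boolean
    ``fixed`` mask are held at their input values on every projection, so
    calibrated correlations survive the repair and only the default-filled
    entries move.  Returns the repaired matrix and the largest absolute
    adjustment of any free entry.
    """
    corr = np.asarray(corr, dtype=float)
    if fixed is None:
        fixed = np.zeros_like(corr, dtype=bool)
    cache_key = corr.tobytes() + fixed.tobytes()
    if cache_key in _PSD_CACHE:
        out, adjustment = _PSD_CACHE[cache_key]
        return out.copy(), adjustment
    out = corr.copy()
    converged = False
    for _ in range(max_iter):
        vals, vecs = np.linalg.eigh(out)
        if vals.min() >= -1e-6:
            converged = True
            break
        out = (vecs * np.maximum(vals, tol)) @ vecs.T
        out = (out + out.T) / 2.0
        np.fill_diagonal(out, 1.0)
        out[fixed] = corr[fixed]
        out = np.clip(out, -1.0, 1.0)
    if not converged:
        # feasibility not reached with the constraints held; release them for
        # a final unconstrained clip so sampling stays well defined
        vals, vecs = np.linalg.eigh(out)
        out = (vecs * np.maximum(vals, tol)) @ vecs.T
        d = np.sqrt(np.diag(out))
        out = np.clip(out / np.outer(d, d), -1.0, 1.0)
        np.fill_diagonal(out, 1.0)
        logger.warning(
            "constrained PSD repair did not converge; pinned correlations "
            "moved by up to %.4f", float(np.abs((out - corr)[fixed]).max() if fixed.any() else 0),
        )
    # guarantee strict positive definiteness for the Cholesky factor: floor the
    # eigenvalues, then restore the unit diagonal by congruence (PSD-preserving)
    vals, vecs = np.linalg.eigh(out)
    if vals.min() < tol:
        out = (vecs * np.maximum(vals, tol)) @ vecs.T
        out = (out + out.T) / 2.0
        d = np.sqrt(np.diag(out))
        out = out / np.outer(d, d)
        np.fill_diagonal(out, 1.0)
    adjustment = float(np.abs((out - corr)[~fixed]).max()) if (~fixed).any() else 0.0
    _PSD_CACHE[cache_key] = (out.copy(), adjustment)
    return out, adjustment


def _build_correlation_matrix(config: GeneratorConfig, group_idx: int) -> np.ndarray:
    names = [f for f in BASE_CONTINUOUS if f in config.feature_params]
    d = len(names)
    idx = {n: i for i, n in enumerate(names)}
    morpho = set(MORPHOMETRIC_BASE)
    corr = np.zeros((d, d))
    fixed = np.zeros((d, d), dtype=bool)
    for i, fi in enumerate(names):
        for j in range(i + 1, d):
            fj = names[j]
            if fi in morpho and fj in morpho:
                corr[i, j] = config.default_correlation
    for (fx, fy), (rho_a, rho_b) in config.pinned_correlations.items():
        if fx in idx and fy in idx:
            i, j = sorted((idx[fx], idx[fy]))
            corr[i, j] = (rho_a, rho_b)[group_idx]
            fixed[i, j] = fixed[j, i] = True
    for (fx, fy), rho in config.correlation_overrides.items():
        rho_g = rho[group_idx] if isinstance(rho, (tuple, list)) else float(rho)
        i, j = sorted((idx[fx], idx[fy]))
        corr[i, j] = rho_g
        fixed[i, j] = fixed[j, i] = True
    corr = corr + corr.T
    np.fill_diagonal(corr, 1.0)
    repaired, adjustment = nearest_positive_semidefinite(corr, fixed=fixed)
    if adjustment > 1e-12:
        logger.info(
            "correlation matrix for group %s adjusted to nearest feasible PSD "
            "(max free-entry |delta| = %.4f; calibrated entries held fixed)",
            "AB"[group_idx], adjustment,
        )
    return repaired


# --------------------------------------------------------------------------
# Truncated-normal moment matching
# --------------------------------------------------------------------------

_TRUNC_CACHE: dict[tuple[float, float], tuple[float, float]] = {}


def _matched_truncnorm_params(mean: float, sd: float) -> tuple[float, float]:
    """Underlying (mu, sigma) so that N(mu, sigma) truncated at 0 has the
    requested mean and SD.  Requires sd < mean is not necessary, but the
    coefficient of variation must be < 1 (the truncated-normal supremum)."""
    key = (round(mean, 10), round(sd, 10))
    if key in _TRUNC_CACHE:
        return _TRUNC_CACHE[key]
    if mean <= 0:
        raise ValueError("truncated features need a positive configured mean")
    if sd / mean >= 0.995:
        raise ValueError(
            f"coefficient of variation {sd / mean:.3f} infeasible for a 0-truncated normal"
        )
    if mean / sd >= 8.0:  # truncation mass < 1e-15: no correction needed
        _TRUNC_CACHE[key] = (mean, sd)
        return mean, sd

    def residual(params):
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        a = -mu / sigma
        m, v = stats.truncnorm.stats(a, np.inf, loc=mu, scale=sigma, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.root(residual, x0=[mean, np.log(sd)], method="hybr")
    if not sol.success:
        raise RuntimeError(f"moment matching failed for mean={mean}, sd={sd}: {sol.message}")
    mu, sigma = float(sol.x[0]), float(np.exp(sol.x[1]))
    _TRUNC_CACHE[key] = (mu, sigma)
    return mu, sigma


def _sample_group(
    n: int, config: GeneratorConfig, group_idx: int, rng: np.random.Generator
) -> pd.DataFrame:
    names = [f for f in BASE_CONTINUOUS if f in config.feature_params]
    corr = _build_correlation_matrix(config, group_idx)
    chol = np.linalg.cholesky(corr + 1e-8 * np.eye(len(names)))
    z = rng.standard_normal((n, len(names))) @ chol.T
    nonneg = set(MORPHOMETRIC_BASE)
    data = {}
    for j, name in enumerate(names):
        ma, sa, mb, sb = config.feature_params[name]
        mean, sd = (ma, sa) if group_idx == 0 else (mb, sb)
        if sd == 0:
            data[name] = np.full(n, mean)
        elif name in nonneg:
            mu, sigma = _matched_truncnorm_params(mean, sd)
            u = np.clip(special.ndtr(z[:, j]), 1e-12, 1.0 - 1e-12)
            a = -mu / sigma
            data[name] = stats.truncnorm.ppf(u, a, np.inf, loc=mu, scale=sigma)
        else:
            data[name] = mean + sd * z[:, j]
    for name, groups in config.categorical_probs.items():
        probs = groups[group_idx]
        levels = [lvl for lvl in CATEGORICAL_LEVELS[name] if lvl in probs]
        p = np.array([probs[lvl] for lvl in levels])
        data[name] = rng.choice(levels, size=n, p=p / p.sum())
    return pd.DataFrame(data)


def sample_feature_table(config: GeneratorConfig | None = None, seed: int | None = None) -> pd.DataFrame:
    """Draw a synthetic cohort with all 41 features plus the group label.

    A fixed seed gives bit-identical output.  Records with a zero ratio
    denominator (possible only under degenerate configurations) are resampled
    and the count logged.
    """
    config = config or GeneratorConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    config.validate()
    rng = np.random.default_rng(config.seed)
    frames = []
    for group_idx, (label, n) in enumerate(
        ((GROUP_GOOD, config.n_group_a), (GROUP_POOR, config.n_group_b))
    ):
        df = _sample_group(n, config, group_idx, rng)
        resampled = 0
        while True:
            bad = np.zeros(len(df), dtype=bool)
            for name, (_, den) in RATIO_FEATURES.items():
                if den in df:
                    bad |= np.abs(df[den].to_numpy(float)) < 1e-12
            if not bad.any():
                break
            resampled += int(bad.sum())
            redraw = _sample_group(int(bad.sum()), config, group_idx, rng)
            df.loc[bad, redraw.columns] = redraw.to_numpy()
        if resampled:
            logger.info("group %s: resampled %d records with zero ratio denominators",
                        label, resampled)
        df[LABEL_COLUMN] = label
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    for name, (a, b) in DIFFERENCE_FEATURES.items():
        table[name] = table[a] - table[b]
    for name, (num, den) in RATIO_FEATURES.items():
        table[name] = table[num] / table[den]
    return table[list(FEATURE_NAMES) + [LABEL_COLUMN]]


# --------------------------------------------------------------------------
# Parametric mask renderer
# --------------------------------------------------------------------------


class GeometryError(ValueError):
    """The configured geometry cannot be rendered in the image."""


@dataclass
class MaskGeometry:
    """Parametric description of an annotated macular-hole B-scan crop.

    All physical quantities are in um.  The cavity's horizontal width profile
    is piecewise linear through anchors at the retina top (green band gap),
    each band boundary (OPL / ELM / EZ gaps), each band's mid-row (per-band
    gaps, the band waists) and the hole base at the RPE (base diameter).
    ``irf_blobs`` are (center_row, center_col, radius_row, radius_col)
    ellipses in pixels, painted strictly inside a band away from the cavity.
    """

    image_size: tuple[int, int] = (256, 256)
    pixel_pitch: float = DEFAULT_PITCH_UM
    layer_thicknesses: dict[str, float] = field(
        default_factory=lambda: {"green": 110.0, "yellow": 80.0, "sky_blue": 25.0, "blue": 25.0}
    )
    boundary_gaps: dict[str, float] = field(
        default_factory=lambda: {"OPL": 465.0, "ELM": 320.0, "EZ": 360.0}
    )
    band_gaps: dict[str, float] = field(
        default_factory=lambda: {"green": 460.0, "yellow": 313.0, "sky_blue": 297.0, "blue": 372.0}
    )
    base_diameter: float = 724.0
    min_linear_diameter: float | None = None
    top_margin: float | None = None  # um; None centres the retina vertically
    irf_blobs: tuple[tuple[int, int, int, int], ...] = ()
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_size
        width_um = w * self.pixel_pitch
        gaps = list(self.boundary_gaps.values()) + list(self.band_gaps.values()) + [
            self.base_diameter
        ]
        if self.min_linear_diameter is not None:
            gaps.append(self.min_linear_diameter)
            if self.min_linear_diameter > self.base_diameter:
                raise GeometryError("min_linear_diameter exceeds base_diameter")
        for g in gaps:
            if g < 0:
                raise GeometryError("gaps must be nonnegative")
            if g > width_um:
                raise GeometryError(f"gap {g} um exceeds image width {width_um} um")
        thickness_px = sum(
            max(1, round(t / self.pixel_pitch)) for t in self.layer_thicknesses.values()
        )
        margin_px = 0 if self.top_margin is None else round(self.top_margin / self.pixel_pitch)
        if thickness_px + margin_px > h:
            raise GeometryError("bands do not fit vertically in the image")


_BAND_ORDER = ("green", "yellow", "sky_blue", "blue")
_BAND_CLASS = {
    "green": octfeat.GREEN,
    "yellow": octfeat.YELLOW,
    "sky_blue": octfeat.SKY_BLUE,
    "blue": octfeat.BLUE,
}
_BAND_SDL_NAME = {
    "green": "Green-sDL",
    "yellow": ONL_SDL,
    "sky_blue": "Sky blue-sDL",
    "blue": "Blue-sDL",
}


def render_synthetic_mask(geometry: MaskGeometry | None = None) -> tuple[LayerMask, dict]:
    """Rasterise the geometry; return the mask and its ground-truth features.

    The ground truth is computed from the *rasterised* width profile with the
    same measurement conventions as the extractor (boundary DL = missing-gap
    width, band sDL = minimum pixel-centre distance, hole diameters =
    horizontal cavity runs), so extraction recovers it exactly up to
    rasterisation of the configured values.
    """
    geometry = geometry or MaskGeometry()
    geometry.validate()
    h, w = geometry.image_size
    pitch = geometry.pixel_pitch
    cx = w // 2

    t_px = {b: max(1, round(geometry.layer_thicknesses[b] / pitch)) for b in _BAND_ORDER}
    total = sum(t_px.values())
    if geometry.top_margin is None:
        r_top = (h - total) // 2
    else:
        r_top = round(geometry.top_margin / pitch)
    if r_top < 1 or r_top + total > h - 1:
        raise GeometryError("retina does not fit vertically with the requested margin")

    # band row ranges and boundary rows
    rows = {}
    r = r_top
    for b in _BAND_ORDER:
        rows[b] = (r, r + t_px[b])
        r += t_px[b]
    b_opl, b_elm, b_ez = rows["yellow"][0], rows["sky_blue"][0], rows["blue"][0]
    r_bottom = rows["blue"][1]  # first row below the retina (RPE level)

    # width-profile anchors (row position -> width in um)
    anchor_rows = [float(r_top)]
    anchor_vals = [geometry.band_gaps["green"]]
    for name, brow in (("OPL", b_opl), ("ELM", b_elm), ("EZ", b_ez)):
        anchor_rows.append(brow - 0.5)
        anchor_vals.append(geometry.boundary_gaps[name])
    for b in _BAND_ORDER[1:]:
        lo, hi = rows[b]
        mid = (lo + hi - 1) / 2.0
        val = geometry.band_gaps[b]
        if b == "yellow" and geometry.min_linear_diameter is not None:
            val = min(val, geometry.min_linear_diameter)
        anchor_rows.append(mid)
        anchor_vals.append(val)
    anchor_rows.append(float(r_bottom - 1))
    anchor_vals.append(geometry.base_diameter)
    order = np.argsort(anchor_rows, kind="stable")
    anchor_rows = np.asarray(anchor_rows)[order]
    anchor_vals = np.asarray(anchor_vals)[order]

    profile_rows = np.arange(r_top, r_bottom)
    w_um = np.interp(profile_rows, anchor_rows, anchor_vals)
    w_px = np.maximum(np.rint(w_um / pitch).astype(int), 0)
    w_px = np.minimum(w_px, w - 2)  # keep at least one band pixel on each side

    labels = np.zeros((h, w), dtype=np.uint8)
    for b in _BAND_ORDER:
        lo, hi = rows[b]
        labels[lo:hi, :] = _BAND_CLASS[b]
    for i, rr in enumerate(profile_rows):
        g = w_px[i]
        if g > 0:
            start = cx - g // 2
            labels[rr, start:start + g] = octfeat.BACKGROUND

    width_of = dict(zip(profile_rows.tolist(), w_px.tolist()))

    # IRF blobs: strictly interior to one band, one-pixel margin from the
    # cavity and from the band's boundary rows so they cannot change any
    # length ground truth.
    yy, xx = np.mgrid[0:h, 0:w]
    for (crow, ccol, ry, rx) in geometry.irf_blobs:
        if ry < 1 or rx < 1:
            raise GeometryError("IRF blob radii must be >= 1 px")
        ellipse = ((yy - crow) / ry) ** 2 + ((xx - ccol) / rx) ** 2 <= 1.0
        grown = np.zeros_like(ellipse)
        grown[max(0, crow - ry - 1):crow + ry + 2, max(0, ccol - rx - 1):ccol + rx + 2] = (
            ((yy - crow) / (ry + 1)) ** 2 + ((xx - ccol) / (rx + 1)) ** 2
        )[max(0, crow - ry - 1):crow + ry + 2, max(0, ccol - rx - 1):ccol + rx + 2] <= 1.0
        touched = np.unique(labels[grown])
        if len(touched) != 1 or touched[0] not in _BAND_CLASS.values():
            raise GeometryError(
                f"IRF blob at ({crow},{ccol}) is not strictly interior to a single band"
            )
        labels[ellipse] = octfeat.RED

    mask = LayerMask(labels, pitch, pitch, provenance="synthetic")

    # ---- ground truth from the rasterised profile -------------------------
    def boundary_gap(brow: int) -> int:
        above = width_of.get(brow - 1, 0)
        below = width_of.get(brow, 0)
        return max(above, below)

    def band_min(b: str) -> int:
        lo, hi = rows[b]
        vals = [width_of[r] for r in range(lo, hi)]
        return min(vals)

    gt: dict[str, float] = {}
    gt["OPL-DL"] = boundary_gap(b_opl) * pitch
    gt["ELM-DL"] = boundary_gap(b_elm) * pitch
    gt["EZ-DL"] = boundary_gap(b_ez) * pitch
    for b in _BAND_ORDER:
        m = band_min(b)
        gt[_BAND_SDL_NAME[b]] = (m + 1) * pitch if m > 0 else 0.0
    cavity = [g for g in w_px if g > 0]
    if cavity:
        gt["Hole-min"] = min(cavity) * pitch
        deepest = max(r for r, g in width_of.items() if g > 0)
        gt["BDM"] = width_of[deepest] * pitch
    else:
        gt["Hole-min"] = gt["BDM"] = 0.0
    counts = np.bincount(labels.ravel(), minlength=6)
    gt["Area IRF"] = float(counts[octfeat.RED])
    gt["Area-green"] = float(counts[octfeat.GREEN])
    gt["Area-yellow"] = float(counts[octfeat.YELLOW])
    gt["Area-sky_blue"] = float(counts[octfeat.SKY_BLUE])
    gt["Area-blue"] = float(counts[octfeat.BLUE])
    for name, (a, b) in DIFFERENCE_FEATURES.items():
        gt[name] = gt[a] - gt[b]
    for name, (num, den) in RATIO_FEATURES.items():
        if gt[den] != 0:
            gt[name] = gt[num] / gt[den]
    return mask, gt


def random_geometry(seed: int | np.random.Generator = 0, with_irf: bool = True) -> MaskGeometry:
    """A plausible random hole geometry, for round-trip testing and demos."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pitch = DEFAULT_PITCH_UM
    thick = {
        "green": rng.uniform(90, 130),
        "yellow": rng.uniform(60, 100),
        "sky_blue": rng.uniform(20, 34),
        "blue": rng.uniform(20, 34),
    }
    boundary = {
        "OPL": rng.uniform(300, 600),
        "ELM": rng.uniform(250, 500),
        "EZ": rng.uniform(250, 550),
    }
    band = {
        "green": rng.uniform(300, 600),
        "yellow": rng.uniform(200, 450),
        "sky_blue": rng.uniform(200, 450),
        "blue": rng.uniform(250, 500),
    }
    base = rng.uniform(620, 900)
    geo = MaskGeometry(
        layer_thicknesses=thick, boundary_gaps=boundary, band_gaps=band,
        base_diameter=base, seed=int(rng.integers(2**31)),
    )
    if with_irf:
        # place two blobs in the yellow band, clear of cavity and boundaries
        t_green = max(1, round(thick["green"] / pitch))
        t_yellow = max(1, round(thick["yellow"] / pitch))
        h = geo.image_size[0]
        total = sum(max(1, round(t / pitch)) for t in thick.values())
        r_top = (h - total) // 2
        crow = r_top + t_green + t_yellow // 2
        ry = max(1, min(4, t_yellow // 2 - 3))
        if ry >= 1 and t_yellow >= 9:
            max_half = max(boundary["OPL"], boundary["ELM"], band["yellow"]) / pitch / 2
            offset = int(max_half + rng.uniform(12, 25))
            rx = int(rng.uniform(6, 12))
            cxc = geo.image_size[1] // 2
            blobs = []
            for sign in (-1, 1):
                ccol = cxc + sign * (offset + rx)
                if 2 + rx < ccol < geo.image_size[1] - rx - 2:
                    blobs.append((crow, ccol, ry, rx))
            geo = replace(geo, irf_blobs=tuple(blobs))
    return geo
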