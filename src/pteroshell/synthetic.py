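"""Synthetic datasets with the statistical structure the analysis assumes.

Every stage of the pipeline is testable without the archived study data:
this module generates speciated water conditions, individual transparency
records, shell micrographs with known mean intensity, duration-deficit
tables and TMM-like expression matrices with planted Omega-correlated
genes. All generators are pure functions of (config, seed).

What is emulated — five seasonal experiments x three CO2 treatments with
the published mean/SD saturation states; transparency from the power-law
T = alpha * Omega^b with a linear duration deficit (anchored at the 4-day
calibration point) for the medium/high treatments, additive Gaussian
noise and a biological floor; seasonal Day-0 transparencies consistent
with the alpha calibration line; expression profiles constructed to have
exact sample correlations with Omega. What is not — measurement drift,
mortality, within-carboy covariance, or sequencing count noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage import draw as skdraw

from .calibration import ALPHA_LINE_INTERCEPT, ALPHA_LINE_SLOPE
from .datasets import SEASONS, TREATMENTS, seasonal_treatment_chemistry
from .imaging import ShellImage

__all__ = [
    "GeneratorConfig",
    "SyntheticShellImage",
    "generate_omega_samples",
    "generate_transparency_dataset",
    "generate_duration_deficits",
    "generate_shell_images",
    "generate_expression_matrix",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters for all generators.

    Defaults mirror the seasonal exposure design: five seasons x three
    treatments with the published Omega means/SDs, durations {1.5, 4, 8,
    15} days, seven individuals per cell, transparency noise SD 0.03 and
    a biological floor of 0.40; power-law exponent 0.255, duration slope
    -0.0238 / day, deficit intercept 0.1026; expression design of 36
    samples with 229 genes planted above the |R| > 0.5 filter, of which
    30 above R^2 > 0.4.
    """

    seed: int = 0
    n_seasons: int = 5
    treatments: pd.DataFrame | None = None  # defaults to the published table
    durations_days: tuple[float, ...] = (1.5, 4.0, 8.0, 15.0)
    n_per_cell: int = 7
    noise_sd_transparency: float = 0.03
    transparency_floor: float = 0.40
    alpha_range: tuple[float, float] = (0.55, 0.82)
    exponent_b: float = 0.255
    duration_slope: float = -0.0238
    beta: float = 0.1026
    day4_anchor: float = 4.0
    n_genes: int = 2000
    n_strong: int = 229
    n_very_strong: int = 30

    def __post_init__(self) -> None:
        if not self.n_very_strong <= self.n_strong <= self.n_genes:
            raise ValueError("need n_very_strong <= n_strong <= n_genes")
        if self.n_seasons < 1 or self.n_per_cell < 1:
            raise ValueError("n_seasons and n_per_cell must be positive")
        if self.noise_sd_transparency < 0:
            raise ValueError("noise SD must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def treatment_table(self) -> pd.DataFrame:
        tbl = self.treatments
        if tbl is None:
            tbl = seasonal_treatment_chemistry()
        seasons = [s for s in tbl["season"].unique()][: self.n_seasons]
        return tbl[tbl["season"].isin(seasons)]


def generate_omega_samples(
    config: GeneratorConfig, n_per_cell: int | None = None
) -> pd.DataFrame:
    """Draw per-individual saturation states from the treatment conditions.

    Omega for each (season, treatment) cell is Gaussian around the
    published mean with the published SD, truncated at a small positive
    value.
    """
    rng = config.rng()
    n = n_per_cell if n_per_cell is not None else config.n_per_cell
    rows = []
    for _, cell in config.treatment_table().iterrows():
        omega = rng.normal(cell["omega_ar"], cell["omega_sd"], size=n)
        omega = np.clip(omega, 0.05, None)
        for w in omega:
            rows.append(
                {"season": cell["season"], "treatment": cell["treatment"],
                 "omega_ar": float(w)}
            )
    return pd.DataFrame(rows)


def _season_alphas(config: GeneratorConfig, rng: np.random.Generator) -> dict:
    lo, hi = config.alpha_range
    seasons = list(config.treatment_table()["season"].unique())
    return {s: float(rng.uniform(lo, hi)) for s in seasons}


def generate_transparency_dataset(config: GeneratorConfig) -> pd.DataFrame:
    """Individual-level transparency records for the full seasonal design.

    Per record: Omega is drawn from its treatment distribution, and

        T = alpha_s * Omega^b                      (ambient)
        T = alpha_s * Omega^b + slope * (D - 4)    (medium/high)

    plus Gaussian noise, floored at the biological limit. The duration
    term is anchored at the 4-day calibration point so the 4-day records
    follow the bare power law; ambient exposures sit above the response
    threshold and carry no duration effect. Each season also carries the
    Day-0 field transparency implied by its alpha through the calibration
    line, and the generating alpha as ``true_alpha``.
    """
    rng = config.rng()
    alphas = _season_alphas(config, rng)
    rows = []
    counter = 0
    for _, cell in config.treatment_table().iterrows():
        season, treatment = cell["season"], cell["treatment"]
        alpha = alphas[season]
        day0 = (alpha - ALPHA_LINE_INTERCEPT) / ALPHA_LINE_SLOPE
        for dur in config.durations_days:
            omega = np.clip(
                rng.normal(cell["omega_ar"], cell["omega_sd"], config.n_per_cell),
                0.05, None,
            )
            t = alpha * omega**config.exponent_b
            if treatment in ("medium", "high"):
                t = t + config.duration_slope * (dur - config.day4_anchor)
            if config.noise_sd_transparency > 0:
                t = t + rng.normal(0, config.noise_sd_transparency, t.shape)
            t = np.maximum(t, config.transparency_floor)
            for w, ti in zip(omega, t):
                counter += 1
                rows.append(
                    {
                        "individual_id": f"{season}-{treatment}-d{dur:g}-{counter}",
                        "season": season,
                        "treatment": treatment,
                        "omega_ar": float(w),
                        "duration_days": float(dur),
                        "transparency": float(min(ti, 1.0)),
                        "day0_transparency": day0,
                        "true_alpha": alpha,
                    }
                )
    return pd.DataFrame(rows)


def generate_duration_deficits(config: GeneratorConfig) -> pd.DataFrame:
    """Transparency-deficit table following the linear duration model.

    Emulates the duration regression's own view of the data: for each
    medium/high treatment and duration, ``n_per_cell`` deficits
    (observed minus predicted Day-4 transparency) are drawn from
    deficit = slope * D + beta plus Gaussian noise.
    """
    rng = config.rng()
    rows = []
    for treatment in ("medium", "high"):
        for dur in config.durations_days:
            noise = rng.normal(0, config.noise_sd_transparency, config.n_per_cell)
            for eps in noise:
                rows.append(
                    {
                        "treatment": treatment,
                        "duration_days": float(dur),
                        "deficit": float(
                            config.duration_slope * dur + config.beta + eps
                        ),
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class SyntheticShellImage:
    """A generated micrograph with its ground truth."""

    image: ShellImage
    target_transparency: float
    exclusions: list  # polygons covering punched holes/apertures
    shell_mask_true: np.ndarray  # ellipse pixels still scoreable
    hole_mask_true: np.ndarray


def _circle_polygon(r0: float, c0: float, radius: float, n: int = 32) -> np.ndarray:
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([r0 + radius * np.sin(ang), c0 + radius * np.cos(ang)])


def generate_shell_images(
    transparency_targets,
    config: GeneratorConfig | None = None,
    size: int = 96,
    texture_amplitude: int = 6,
    n_holes: int = 0,
    hole_value: int = 40,
) -> list[SyntheticShellImage]:
    """Generate white-background micrographs with known mean shell intensity.

    Each image holds one elliptical "shell" whose pixel intensities are
    integer-dithered and pair-jittered so their mean equals
    ``target * 255`` to within one grey level; optional punched holes are
    dark (shadowed aperture) discs, each covered by a matching exclusion
    polygon. A target of 1.0 yields an all-255 shell.
    """
    config = config or GeneratorConfig()
    rng = config.rng()
    out = []
    for target in np.atleast_1d(np.asarray(transparency_targets, dtype=float)):
        if not 0.0 < target <= 1.0:
            raise ValueError(f"transparency target {target} outside (0, 1]")
        canvas = np.full((size, size), 255, dtype=np.int16)
        r0, c0 = size / 2 + rng.uniform(-3, 3), size / 2 + rng.uniform(-3, 3)
        radii = (size * 0.32 * rng.uniform(0.9, 1.0),
                 size * 0.24 * rng.uniform(0.9, 1.0))
        rr, cc = skdraw.ellipse(r0, c0, *radii, shape=canvas.shape,
                                rotation=rng.uniform(0, np.pi))
        n_px = rr.size
        base = target * 255.0
        lo = int(np.floor(base))
        vals = np.full(n_px, lo, dtype=np.int16)
        n_hi = int(round((base - lo) * n_px))
        if n_hi:
            vals[rng.choice(n_px, size=n_hi, replace=False)] += 1
        amp = int(min(texture_amplitude, lo, 254 - lo - 1))
        if amp > 0 and n_px >= 2:
            order = rng.permutation(n_px)
            half = n_px // 2
            jitter = rng.integers(0, amp + 1, size=half)
            vals[order[:half]] += jitter
            vals[order[half: 2 * half]] -= jitter
        canvas[rr, cc] = vals

        ellipse_mask = np.zeros(canvas.shape, dtype=bool)
        ellipse_mask[rr, cc] = True
        hole_mask = np.zeros(canvas.shape, dtype=bool)
        exclusions = []
        for _ in range(n_holes):
            hr = rng.uniform(2.5, min(radii) * 0.35)
            hrow = r0 + rng.uniform(-0.3, 0.3) * radii[0]
            hcol = c0 + rng.uniform(-0.3, 0.3) * radii[1]
            hrr, hcc = skdraw.disk((hrow, hcol), hr, shape=canvas.shape)
            canvas[hrr, hcc] = hole_value
            hole_mask[hrr, hcc] = True
            exclusions.append(_circle_polygon(hrow, hcol, hr + 1.5))
        out.append(
            SyntheticShellImage(
                image=ShellImage(
                    np.clip(canvas, 0, 255).astype(np.uint8),
                    image_id=f"synthetic_{len(out):03d}",
                ),
                target_transparency=float(target),
                exclusions=exclusions,
                shell_mask_true=ellipse_mask & ~hole_mask,
                hole_mask_true=hole_mask,
            )
        )
    return out


def generate_expression_matrix(
    config: GeneratorConfig | None = None,
    seasons: tuple[str, ...] = ("Jan14", "Apr14", "Aug14", "Nov14"),
    n_replicates: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TMM-like expression matrix with planted Omega-correlated genes.

    36 samples (four seasons x three treatments x three replicates) carry
    per-sample saturation states drawn around the published cell means.
    Planted genes are constructed on the log(x+1) scale with *exact*
    sample Pearson correlation against Omega — |R| in (0.52, 0.60) for
    the strong-only set and (0.68, 0.85) for the very-strong set, random
    sign — so screen pass counts match the planted counts up to
    background false positives. Background genes are Omega-independent
    with gene-specific seasonal block effects and lognormal-scale noise.

    Returns
    -------
    (values, meta): genes x samples DataFrame of non-negative abundances,
    and a per-sample metadata table (sample_id, season, treatment,
    omega_ar).
    """
    config = config or GeneratorConfig()
    rng = config.rng()
    chem = seasonal_treatment_chemistry().set_index(["season", "treatment"])
    meta_rows = []
    for season in seasons:
        for treatment in TREATMENTS:
            cell = chem.loc[(season, treatment)]
            for rep in range(1, n_replicates + 1):
                omega = float(
                    np.clip(rng.normal(cell["omega_ar"], cell["omega_sd"]), 0.05, None)
                )
                meta_rows.append(
                    {
                        "sample_id": f"{season}_{treatment}_r{rep}",
                        "season": season,
                        "treatment": treatment,
                        "omega_ar": omega,
                    }
                )
    meta = pd.DataFrame(meta_rows)
    omega = meta["omega_ar"].to_numpy()
    n = omega.size

    yc = omega - omega.mean()
    u_y = yc / np.linalg.norm(yc)

    def exact_r_profile(r_target: float) -> np.ndarray:
        """Unit-norm centered vector with exact sample correlation r_target."""
        e = rng.normal(size=n)
        e = e - e.mean()
        e = e - (e @ u_y) * u_y
        u_e = e / np.linalg.norm(e)
        return r_target * u_y + np.sqrt(1.0 - r_target**2) * u_e

    n_strong_only = config.n_strong - config.n_very_strong
    n_background = config.n_genes - config.n_strong
    log_values = np.empty((config.n_genes, n))
    gene_ids = []
    truth = []

    for i in range(config.n_strong):
        if i < config.n_very_strong:
            r = rng.uniform(0.68, 0.85)
            label = "very_strong"
        else:
            r = rng.uniform(0.52, 0.60)
            label = "strong"
        r *= rng.choice([-1.0, 1.0])
        mu = rng.uniform(2.0, 5.0)
        scale = rng.uniform(0.6, 1.5)
        log_values[i] = mu + scale * exact_r_profile(r)
        gene_ids.append(f"planted_{label}_{i:04d}")
        truth.append(r)

    season_codes = meta["season"].map({s: k for k, s in enumerate(seasons)})
    season_onehot = np.eye(len(seasons))[season_codes.to_numpy()]
    for j in range(n_background):
        i = config.n_strong + j
        mu = rng.uniform(0.5, 5.0)
        block = season_onehot @ rng.normal(0, 0.6, size=len(seasons))
        noise = rng.normal(0, 0.8, size=n)
        log_values[i] = np.clip(mu + block + noise, 0.0, None)
        gene_ids.append(f"background_{j:04d}")
        truth.append(0.0)

    values = pd.DataFrame(
        np.expm1(log_values), index=gene_ids, columns=meta["sample_id"]
    )
    values.index.name = "gene"
    values.attrs["true_r"] = dict(zip(gene_ids, truth))
    return values, meta
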