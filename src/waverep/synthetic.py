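"""Synthetic cohorts: genotypes with block LD, heritable latent factors,
parametric spirogram/PPG waveforms, covariates and liability-threshold
disease labels, with full ground truth retained.

Everything is driven by explicit integer seeds through
``numpy.random.default_rng``; no global random state.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import multivariate_normal, norm

from .ppg import PPG_LENGTH, PPGRecord
from .spiro import DT, SpirogramRecord, derive_flow_time, to_flow_volume

logger = logging.getLogger(__name__)

E_MINUS_2 = math.e - 2.0


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Dosage matrix with variant metadata.

    ``dosages``: (n_individuals, n_variants) values in [0, 2];
    ``position_bp`` is 1-based and strictly increasing within a chromosome;
    ``maf`` is the declared minor-allele frequency per variant.
    """

    dosages: np.ndarray
    variant_ids: list[str]
    chromosome: np.ndarray
    position_bp: np.ndarray
    maf: np.ndarray

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def standardized(self) -> np.ndarray:
        """Column-standardized dosages (zero mean, unit variance)."""
        d = self.dosages
        sd = d.std(axis=0)
        sd[sd == 0] = 1.0
        return (d - d.mean(axis=0)) / sd


def _binary_corr_from_latent(rho: float, zf: float, f: float) -> float:
    """Pearson correlation of two threshold indicators 1{Z < zf} whose
    latent normals have correlation ``rho``."""
    p11 = multivariate_normal.cdf([zf, zf], mean=[0, 0],
                                  cov=[[1, rho], [rho, 1]])
    return (p11 - f * f) / (f * (1 - f))


def _calibrate_latent_rho(target: float, f: float) -> float:
    """Latent AR(1) parameter so that adjacent-variant genotype correlation
    matches ``target`` at MAF ``f`` (inverts the orthant probability)."""
    if target <= 0:
        return 0.0
    zf = norm.ppf(f)
    hi = 0.999
    if _binary_corr_from_latent(hi, zf, f) <= target:
        return hi
    return brentq(lambda r: _binary_corr_from_latent(r, zf, f) - target,
                  0.0, hi, xtol=1e-4)


def simulate_genotypes(n: int, m: int,
                       maf_range: tuple[float, float] = (0.05, 0.5),
                       ld_block_size: int = 10,
                       ld_rho: float = 0.0,
                       seed: int = 0,
                       spacing_bp: int = 10_000,
                       chromosome: int = 1) -> GenotypeMatrix:
    """Hardy-Weinberg dosages with block-diagonal LD.

    Within each block of ``ld_block_size`` consecutive variants, haplotype
    indicators come from a thresholded Gaussian AR(1) copula calibrated so
    adjacent-variant genotype correlation ~= ``ld_rho``; blocks are
    independent. Deterministic given ``seed``.
    """
    if n < 1 or m < 1:
        raise ValueError("n and m must be >= 1")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must lie in (0, 0.5], got {maf_range}")
    if not (0 <= ld_rho < 1):
        raise ValueError(f"ld_rho must be in [0, 1), got {ld_rho}")
    if ld_block_size < 1:
        raise ValueError("ld_block_size must be >= 1")

    rng = np.random.default_rng(seed)
    maf = rng.uniform(lo, hi, size=m)
    zf = norm.ppf(maf)

    dosages = np.zeros((n, m), dtype=np.float64)
    for start in range(0, m, ld_block_size):
        stop = min(start + ld_block_size, m)
        width = stop - start
        if ld_rho > 0 and width > 1:
            phi = _calibrate_latent_rho(ld_rho, float(maf[start:stop].mean()))
        else:
            phi = 0.0
        # two haplotypes per individual, AR(1) along variants
        z = rng.standard_normal((2 * n, width))
        if phi > 0:
            for j in range(1, width):
                z[:, j] = phi * z[:, j - 1] + math.sqrt(1 - phi * phi) * z[:, j]
        alleles = (z < zf[start:stop]).astype(np.float64)
        dosages[:, start:stop] = alleles[:n] + alleles[n:]

    positions = np.arange(1, m + 1, dtype=np.int64) * spacing_bp
    return GenotypeMatrix(
        dosages=dosages,
        variant_ids=[f"rs{j + 1}" for j in range(m)],
        chromosome=np.full(m, chromosome, dtype=np.int64),
        position_bp=positions,
        maf=maf,
    )


# ---------------------------------------------------------------------------
# latent factors
# ---------------------------------------------------------------------------

@dataclass
class LatentFactorTable:
    """Heritable latent factors with retained ground truth.

    ``factors``: (n, K) with ~unit-variance columns; ``causal_variants[k]``
    lists (variant index, effect size) pairs; ``h2[k]`` is the target
    heritability; ``genetic_scores`` holds the standardized genetic
    component of each factor.
    """

    factors: np.ndarray
    causal_variants: list[list[tuple[int, float]]]
    h2: np.ndarray
    genetic_scores: np.ndarray

    @property
    def n_factors(self) -> int:
        return self.factors.shape[1]


def simulate_factors(G: GenotypeMatrix, n_factors: int,
                     causal_per_factor: int,
                     h2: float | np.ndarray,
                     seed: int = 0,
                     disjoint: bool = True,
                     effect_range: tuple[float, float] | None = None,
                     ) -> LatentFactorTable:
    """factor_k = sqrt(h2_k) * standardized genetic score + sqrt(1-h2_k) * noise.

    The genetic score is a weighted sum of standardized causal dosages,
    itself standardized; causal sets are disjoint across factors by default.
    Effects are standard normal by default; ``effect_range`` instead draws
    |effect| uniformly from the given interval with random sign (bounds the
    per-variant contribution away from zero, useful for power studies).
    """
    h2 = np.broadcast_to(np.asarray(h2, dtype=float), (n_factors,)).copy()
    if np.any((h2 < 0) | (h2 > 1)):
        raise ValueError("h2 must lie in [0, 1]")
    need = causal_per_factor * n_factors if disjoint else causal_per_factor
    if need > G.n_variants:
        raise ValueError(
            f"{need} causal variants requested but only {G.n_variants} exist")

    rng = np.random.default_rng(seed)
    X = G.standardized()
    n = G.n_individuals

    if disjoint:
        pool = rng.permutation(G.n_variants)[:causal_per_factor * n_factors]
        index_sets = pool.reshape(n_factors, causal_per_factor)
    else:
        index_sets = np.vstack([
            rng.choice(G.n_variants, causal_per_factor, replace=False)
            for _ in range(n_factors)])

    factors = np.empty((n, n_factors))
    scores = np.empty((n, n_factors))
    causal: list[list[tuple[int, float]]] = []
    for k in range(n_factors):
        idx = index_sets[k]
        if effect_range is not None:
            lo_e, hi_e = effect_range
            betas = (rng.uniform(lo_e, hi_e, causal_per_factor)
                     * rng.choice([-1.0, 1.0], causal_per_factor))
        else:
            betas = rng.standard_normal(causal_per_factor)
        raw = X[:, idx] @ betas
        sd = raw.std()
        score = (raw - raw.mean()) / (sd if sd > 0 else 1.0)
        eps = rng.standard_normal(n)
        eps = (eps - eps.mean()) / (eps.std() if eps.std() > 0 else 1.0)
        factors[:, k] = math.sqrt(h2[k]) * score + math.sqrt(1 - h2[k]) * eps
        scores[:, k] = score
        causal.append(list(zip(idx.tolist(), betas.tolist())))

    return LatentFactorTable(factors=factors, causal_variants=causal,
                             h2=h2, genetic_scores=scores)


# ---------------------------------------------------------------------------
# waveform renderers
# ---------------------------------------------------------------------------

@dataclass
class SpiroShapeConfig:
    """Factor -> spirogram shape mapping (a documented stand-in; real
    physiology is a non-goal).

    Flow model: Q(t) = PEF * (t/t_p) * exp(1 - t/t_p) for t <= t_p, then
    PEF * exp(-lambda (t - t_p)); volume is the cumulative integral on the
    10 ms grid. Factor 1 shifts FVC, factor 2 scales the decay rate lambda
    (obstruction), factor 3 scales the time-to-peak t_p, and an optional
    factor 4 adds a zero-mean ripple on the decay limb that leaves the five
    EDFs essentially unchanged.
    """

    fvc_base: float = 4.0          # L, reference FVC at factors == 0
    fvc_per_sd: float = 0.4        # L shift per factor-1 SD
    fvc_bounds: tuple[float, float] = (1.5, 6.5)
    lambda_base: float = 2.5       # 1/s decay rate
    lambda_log_per_sd: float = 0.20
    lambda_bounds: tuple[float, float] = (1.0, 6.0)
    tp_base: float = 0.12          # s time of peak flow
    tp_log_per_sd: float = 0.15
    tp_bounds: tuple[float, float] = (0.06, 0.30)
    pef_max: float = 15.0          # L/s cap keeping curves inside QC ranges
    ripple_amp_per_sd: float = 0.0  # relative ripple amplitude per factor-4 SD
    ripple_amp_max: float = 0.45
    ripple_freq_hz: float = 3.0
    ripple_delay_s: float = 0.3    # ripple starts this long after peak flow
    n_samples: int = 1000


def _clip_logged(value: float, bounds: tuple[float, float], name: str) -> float:
    if value < bounds[0] or value > bounds[1]:
        logger.debug("clipped %s=%.3g to %s", name, value, bounds)
        return float(np.clip(value, *bounds))
    return float(value)


def analytic_fvc(pef: float, tp: float, lam: float,
                 ripple_amp: float = 0.0, ripple_freq_hz: float = 0.0,
                 ripple_delay_s: float = 0.0) -> float:
    """Closed-form integral of the flow model over [0, inf)."""
    base = pef * (tp * E_MINUS_2 + 1.0 / lam)
    if ripple_amp and ripple_freq_hz:
        w = 2 * math.pi * ripple_freq_hz
        base += (pef * ripple_amp * math.exp(-lam * ripple_delay_s)
                 * w / (lam * lam + w * w))
    return base


def render_spirogram(factor_values: np.ndarray,
                     config: SpiroShapeConfig | None = None) -> SpirogramRecord:
    """Render one blow from up to four factor values (missing -> 0)."""
    cfg = config or SpiroShapeConfig()
    f = np.zeros(4)
    fv = np.asarray(factor_values, dtype=float).ravel()
    if not np.all(np.isfinite(fv)):
        raise ValueError("factor values must be finite")
    f[:min(4, fv.size)] = fv[:4]

    fvc_target = _clip_logged(cfg.fvc_base + cfg.fvc_per_sd * f[0],
                              cfg.fvc_bounds, "fvc")
    lam = _clip_logged(cfg.lambda_base * math.exp(cfg.lambda_log_per_sd * f[1]),
                       cfg.lambda_bounds, "lambda")
    tp = _clip_logged(cfg.tp_base * math.exp(cfg.tp_log_per_sd * f[2]),
                      cfg.tp_bounds, "tp")
    ripple = 0.0
    if cfg.ripple_amp_per_sd:
        ripple = float(np.clip(cfg.ripple_amp_per_sd * f[3],
                               -cfg.ripple_amp_max, cfg.ripple_amp_max))

    pef = fvc_target / (tp * E_MINUS_2 + 1.0 / lam)
    if pef > cfg.pef_max:
        logger.debug("clipped pef=%.3g to %.3g", pef, cfg.pef_max)
        pef = cfg.pef_max

    t = np.arange(cfg.n_samples) * DT
    rise = pef * (t / tp) * np.exp(1.0 - t / tp)
    dt_decay = t - tp
    decay = pef * np.exp(-lam * np.clip(dt_decay, 0.0, None))
    if ripple:
        # delayed onset keeps peak flow and the first second untouched
        dt_r = np.clip(dt_decay - cfg.ripple_delay_s, 0.0, None)
        decay = decay * (1.0 + ripple * np.sin(
            2 * math.pi * cfg.ripple_freq_hz * dt_r))
    flow = np.where(t <= tp, rise, decay)
    flow = np.clip(flow, 0.0, None)

    volume = np.concatenate([[0.0], np.cumsum((flow[1:] + flow[:-1]) / 2) * DT])
    rec = SpirogramRecord(volume_time=volume, flow_time=flow,
                          acceptability=True)
    rec.flow_volume = to_flow_volume(volume, flow)
    return rec


@dataclass
class PPGShapeConfig:
    """Factor -> pulse shape mapping: a systolic Gaussian bump plus a
    dicrotic Gaussian bump on a 100-sample grid. Factor 1 shifts the
    systolic peak position, factor 2 controls the dicrotic amplitude
    (notch depth), factor 3 the pulse width."""

    systolic_center: float = 25.0
    systolic_shift_per_sd: float = 3.0
    systolic_center_bounds: tuple[float, float] = (15.0, 38.0)
    systolic_width: float = 7.0
    width_log_per_sd: float = 0.12
    width_bounds: tuple[float, float] = (4.0, 12.0)
    dicrotic_center: float = 62.0
    dicrotic_width: float = 9.0
    dicrotic_amp: float = 0.35
    dicrotic_amp_per_sd: float = 0.12
    dicrotic_amp_bounds: tuple[float, float] = (0.0, 0.8)


def render_ppg(factor_values: np.ndarray,
               config: PPGShapeConfig | None = None) -> PPGRecord:
    """Render one 100-sample pulse from up to three factor values."""
    cfg = config or PPGShapeConfig()
    f = np.zeros(3)
    fv = np.asarray(factor_values, dtype=float).ravel()
    if not np.all(np.isfinite(fv)):
        raise ValueError("factor values must be finite")
    f[:min(3, fv.size)] = fv[:3]

    c1 = _clip_logged(cfg.systolic_center + cfg.systolic_shift_per_sd * f[0],
                      cfg.systolic_center_bounds, "systolic_center")
    amp2 = _clip_logged(cfg.dicrotic_amp + cfg.dicrotic_amp_per_sd * f[1],
                        cfg.dicrotic_amp_bounds, "dicrotic_amp")
    width = _clip_logged(cfg.systolic_width * math.exp(cfg.width_log_per_sd * f[2]),
                         cfg.width_bounds, "width")

    t = np.arange(PPG_LENGTH, dtype=float)
    pulse = (np.exp(-0.5 * ((t - c1) / width) ** 2)
             + amp2 * np.exp(-0.5 * ((t - cfg.dicrotic_center)
                                     / cfg.dicrotic_width) ** 2))
    return PPGRecord(samples=pulse)


# ---------------------------------------------------------------------------
# disease labels and full cohorts
# ---------------------------------------------------------------------------

def simulate_disease(factors: LatentFactorTable | np.ndarray,
                     weights: np.ndarray,
                     prevalence: float,
                     seed: int = 0,
                     noise_sd: float = 1.0) -> np.ndarray:
    """Liability-threshold labels: liability = factors @ weights + noise,
    thresholded at the empirical (1 - prevalence) quantile."""
    if not (0 < prevalence < 1):
        raise ValueError("prevalence must be in (0, 1)")
    F = factors.factors if isinstance(factors, LatentFactorTable) else np.asarray(factors)
    w = np.asarray(weights, dtype=float)
    if w.shape != (F.shape[1],):
        raise ValueError(f"weights must have shape ({F.shape[1]},)")
    rng = np.random.default_rng(seed)
    liability = F @ w + noise_sd * rng.standard_normal(F.shape[0])
    threshold = np.quantile(liability, 1.0 - prevalence)
    return (liability > threshold).astype(np.int8)


@dataclass
class SyntheticCohort:
    """All simulated layers for one cohort, ground truth included."""

    genotypes: GenotypeMatrix
    factors: LatentFactorTable
    spirograms: list[SpirogramRecord]
    ppgs: list[PPGRecord]
    covariates: "pd.DataFrame"  # noqa: F821 - imported lazily
    labels: dict[str, np.ndarray]
    continuous_traits: dict[str, np.ndarray] = field(default_factory=dict)
    seed: int = 0

    @property
    def n_individuals(self) -> int:
        return self.genotypes.n_individuals

    def spirogram_matrix(self, channel: str = "both") -> np.ndarray:
        """Stack curves: 'volume', 'flow', 'flow_volume' -> (n, 1000);
        'both' -> (n, 2, 1000) volume+flow channels."""
        if channel == "both":
            return np.stack([
                np.stack([r.volume_time, r.flow_time]) for r in self.spirograms])
        attr = {"volume": "volume_time", "flow": "flow_time",
                "flow_volume": "flow_volume"}[channel]
        return np.stack([getattr(r, attr) for r in self.spirograms])

    def ppg_matrix(self) -> np.ndarray:
        return np.stack([r.samples for r in self.ppgs])


def simulate_cohort(n: int, m: int,
                    n_factors: int = 3,
                    causal_per_factor: int = 5,
                    h2: float | np.ndarray = 0.4,
                    maf_range: tuple[float, float] = (0.05, 0.5),
                    ld_block_size: int = 10,
                    ld_rho: float = 0.0,
                    prevalence: float = 0.1,
                    disease_weights: np.ndarray | None = None,
                    disease_noise_sd: float = 1.0,
                    spiro_config: SpiroShapeConfig | None = None,
                    ppg_config: PPGShapeConfig | None = None,
                    seed: int = 0) -> SyntheticCohort:
    """Compose all layers into one reproducible cohort.

    Spirograms are rendered from factors 1-3 (plus factor 4 as ripple if
    the shape config enables it); PPGs from factors 1-3. One disease
    ("disease") is generated from ``disease_weights`` (default: all weight
    on factor 1).
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    s_geno, s_fact, s_dis, s_cov = (int(x) for x in
                                    rng.integers(0, 2 ** 31, size=4))
    G = simulate_genotypes(n, m, maf_range=maf_range,
                           ld_block_size=ld_block_size, ld_rho=ld_rho,
                           seed=s_geno)
    factors = simulate_factors(G, n_factors, causal_per_factor, h2,
                               seed=s_fact)

    spirograms = [render_spirogram(factors.factors[i], spiro_config)
                  for i in range(n)]
    ppgs = [render_ppg(factors.factors[i], ppg_config) for i in range(n)]

    cov_rng = np.random.default_rng(s_cov)
    sex = cov_rng.integers(0, 2, size=n)
    covariates = pd.DataFrame({
        "age": cov_rng.uniform(40, 70, size=n),
        "sex": sex,
        "height": cov_rng.normal(163, 7, size=n) + 12 * sex,
        "bmi": cov_rng.normal(27, 4, size=n),
    })

    if disease_weights is None:
        disease_weights = np.zeros(n_factors)
        disease_weights[0] = 1.0
    labels = {"disease": simulate_disease(factors, disease_weights,
                                          prevalence, seed=s_dis,
                                          noise_sd=disease_noise_sd)}
    liability_proxy = factors.factors @ np.asarray(disease_weights, dtype=float)
    return SyntheticCohort(genotypes=G, factors=factors,
                           spirograms=spirograms, ppgs=ppgs,
                           covariates=covariates, labels=labels,
                           continuous_traits={"liability_signal": liability_proxy},
                           seed=seed)
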