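"""Synthetic multi-domain community time series with known ground truth.

The generator is a discrete-time (Ricker-form) generalized Lotka-Volterra
map on a monthly grid:

    x_i(t+1) = x_i(t) * exp( r_i + s_i sin(2*pi*t/period + phi_i)
                             + sum_j a_ij x_j(t) + eps_i(t) ),
    eps_i(t) ~ Normal(0, process_noise_sd)

with per-taxon intrinsic rates ``r_i`` (1/month), seasonal forcing of
amplitude ``s_i`` and phase ``phi_i``, per-capita interaction coefficients
``a_ij`` (1/abundance/month, self-limitation on the diagonal) and log-scale
process noise.  Because the update is an explicit map, its Jacobian

    J_ij = d x_i(t+1) / d x_j(t) = x_i(t+1) * a_ij + delta_ij * x_i(t+1)/x_i(t)

is available in closed form (:func:`analytic_jacobian`) and serves as ground
truth for interaction-inference recovery tests.

On top of the deterministic skeleton the module emulates the features of a
long-running activated-sludge monitoring campaign: a one-off mortality pulse
(a bleach-like transient intervention), finite-depth read sampling
(multinomial coverage counts) and an operational-parameter table including a
sustained salinity dip and a covariate deliberately coupled to one taxon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import VALID_DOMAINS, CommunityTimeSeries

__all__ = [
    "GLVParams",
    "InterventionSpec",
    "MetadataConfig",
    "UnstableParametersError",
    "simulate_glv",
    "analytic_jacobian",
    "apply_intervention",
    "sample_coverage",
    "simulate_metadata",
    "random_stable_params",
    "benchmark_glv_params",
    "linear_benchmark_system",
    "BENCHMARK_EFFECT_FLOOR",
    "BENCHMARK_PREDATOR_PREY_PAIR",
]

#: Divergence guard for the simulator.
_ABUNDANCE_CEILING = 1e12


class UnstableParametersError(RuntimeError):
    """Raised when a simulation diverges (non-finite or > 1e12 abundance)."""


@dataclass
class GLVParams:
    """Ground-truth parameters of the discrete-time gLV community model.

    Attributes
    ----------
    n_taxa : int
        Number of taxa.
    growth_rates : ndarray, shape (n_taxa,)
        Intrinsic per-capita growth rates r_i (1/month).
    interaction_matrix : ndarray, shape (n_taxa, n_taxa)
        Per-capita interaction coefficients a_ij (1/abundance/month);
        diagonal entries must be <= 0 (self-limitation).
    seasonal_amplitude : ndarray, shape (n_taxa,)
        Dimensionless seasonal forcing amplitudes s_i.
    seasonal_phase : ndarray, shape (n_taxa,)
        Seasonal phases phi_i in radians.
    period : float
        Forcing period in months (12 = annual).
    process_noise_sd : float
        Standard deviation of the log-scale process noise.
    domain_labels : list of str
        Per-taxon tag in {eukaryote, prokaryote, virus}.
    """

    n_taxa: int
    growth_rates: np.ndarray
    interaction_matrix: np.ndarray
    seasonal_amplitude: np.ndarray | None = None
    seasonal_phase: np.ndarray | None = None
    period: float = 12.0
    process_noise_sd: float = 0.0
    domain_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be positive")
        self.growth_rates = np.broadcast_to(
            np.asarray(self.growth_rates, dtype=float), (self.n_taxa,)
        ).copy()
        self.interaction_matrix = np.asarray(self.interaction_matrix, dtype=float)
        if self.interaction_matrix.shape != (self.n_taxa, self.n_taxa):
            raise ValueError("interaction_matrix must be n_taxa x n_taxa")
        if (np.diag(self.interaction_matrix) > 0).any():
            raise ValueError("diagonal interaction coefficients must be <= 0")
        if self.seasonal_amplitude is None:
            self.seasonal_amplitude = np.zeros(self.n_taxa)
        if self.seasonal_phase is None:
            self.seasonal_phase = np.zeros(self.n_taxa)
        self.seasonal_amplitude = np.broadcast_to(
            np.asarray(self.seasonal_amplitude, dtype=float), (self.n_taxa,)
        ).copy()
        self.seasonal_phase = np.broadcast_to(
            np.asarray(self.seasonal_phase, dtype=float), (self.n_taxa,)
        ).copy()
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.process_noise_sd < 0:
            raise ValueError("process_noise_sd must be non-negative")
        if self.domain_labels is None:
            self.domain_labels = ["prokaryote"] * self.n_taxa
        if len(self.domain_labels) != self.n_taxa:
            raise ValueError("domain_labels length must equal n_taxa")
        bad = set(self.domain_labels) - set(VALID_DOMAINS)
        if bad:
            raise ValueError(f"unknown domain labels: {sorted(bad)}")

    def growth_exponent(self, state: np.ndarray, t: float) -> np.ndarray:
        """Deterministic part of the per-capita log growth at state/time."""
        state = np.asarray(state, dtype=float)
        seasonal = self.seasonal_amplitude * np.sin(
            2.0 * np.pi * t / self.period + self.seasonal_phase
        )
        return self.growth_rates + seasonal + self.interaction_matrix @ state


@dataclass
class InterventionSpec:
    """A one-step multiplicative mortality pulse (bleach-like transient).

    ``survival_fraction`` multiplies the abundance of each affected taxon at
    month ``time_index``; there is no built-in recovery term — the dynamics
    simply continue from the perturbed state.
    """

    time_index: int
    affected_taxa: list[int]
    survival_fraction: float | np.ndarray = 0.5

    def __post_init__(self) -> None:
        frac = np.broadcast_to(
            np.asarray(self.survival_fraction, dtype=float), (len(self.affected_taxa),)
        )
        if ((frac <= 0) | (frac > 1)).any():
            raise ValueError("survival_fraction must lie in (0, 1]")
        self.survival_fraction = frac.copy()


def simulate_glv(
    params: GLVParams,
    n_steps: int,
    initial_state: np.ndarray,
    seed: int,
    intervention: InterventionSpec | None = None,
) -> CommunityTimeSeries:
    """Simulate the Ricker-form gLV map for ``n_steps`` months.

    Parameters
    ----------
    params : GLVParams
    n_steps : int
        Series length (>= 2); the returned series has ``n_steps`` columns.
    initial_state : ndarray
        Strictly positive initial abundances.
    seed : int
        Seed for the process-noise stream; identical seeds give identical
        trajectories.
    intervention : InterventionSpec, optional
        If given, the pulse is applied at its ``time_index`` and the
        post-pulse trajectory continues from the perturbed state.

    Raises
    ------
    UnstableParametersError
        If any abundance becomes non-finite or exceeds 1e12, naming the first
        offending taxon and step.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    x0 = np.asarray(initial_state, dtype=float)
    if x0.shape != (params.n_taxa,):
        raise ValueError("initial_state must have one entry per taxon")
    if (x0 <= 0).any():
        raise ValueError("initial_state must be strictly positive")
    if intervention is not None and not 0 <= intervention.time_index < n_steps:
        raise ValueError("intervention time_index outside the simulated range")

    rng = np.random.default_rng(seed)
    out = np.empty((params.n_taxa, n_steps))
    x = x0.copy()
    if intervention is not None and intervention.time_index == 0:
        x[intervention.affected_taxa] *= intervention.survival_fraction
    out[:, 0] = x
    for t in range(n_steps - 1):
        growth = params.growth_exponent(x, t)
        if params.process_noise_sd > 0:
            growth = growth + rng.normal(0.0, params.process_noise_sd, params.n_taxa)
        x = x * np.exp(growth)
        _check_finite(x, params, step=t + 1)
        if intervention is not None and intervention.time_index == t + 1:
            x = x.copy()
            x[intervention.affected_taxa] *= intervention.survival_fraction
        out[:, t + 1] = x
    return CommunityTimeSeries(
        abundances=out,
        time_stamps=np.arange(n_steps),
        taxon_ids=[f"taxon_{i:02d}" for i in range(params.n_taxa)],
        domain_labels=list(params.domain_labels),
    )


def _check_finite(x: np.ndarray, params: GLVParams, step: int) -> None:
    bad = ~np.isfinite(x) | (x > _ABUNDANCE_CEILING)
    if bad.any():
        i = int(np.argmax(bad))
        raise UnstableParametersError(
            f"unstable parameters: taxon {i} ({params.domain_labels[i]}) "
            f"diverged at step {step} (value={x[i]!r})"
        )


def analytic_jacobian(params: GLVParams, state: np.ndarray, t: int) -> np.ndarray:
    """Closed-form Jacobian of the noise-free update map at ``state``.

    J_ij = x_i(t+1) * a_ij + delta_ij * x_i(t+1) / x_i(t), evaluated with the
    process noise at its mean (0).  For i != j the sign of J_ij equals the
    sign of a_ij whenever x_i(t+1) > 0.
    """
    x = np.asarray(state, dtype=float)
    if (x <= 0).any():
        raise ValueError("state must be strictly positive")
    x_next = x * np.exp(params.growth_exponent(x, t))
    jac = x_next[:, None] * params.interaction_matrix
    jac[np.diag_indices(params.n_taxa)] += x_next / x
    return jac


def apply_intervention(
    series: CommunityTimeSeries, spec: InterventionSpec
) -> CommunityTimeSeries:
    """Multiply abundances at ``spec.time_index`` by the survival fractions.

    Only the listed taxa at the listed month change; every other entry is
    untouched.  Note that this edits a finished series — to let the dynamics
    respond to the pulse, pass the spec to :func:`simulate_glv` instead.
    """
    if not 0 <= spec.time_index < series.n_time:
        raise ValueError(
            f"time_index {spec.time_index} out of range for series of length {series.n_time}"
        )
    out = series.copy()
    out.abundances[spec.affected_taxa, spec.time_index] *= spec.survival_fraction
    return out


def sample_coverage(
    series: CommunityTimeSeries,
    library_size: int,
    feature_lengths: np.ndarray,
    seed: int,
) -> pd.DataFrame:
    """Draw finite-depth coverage counts from a community series.

    Emulates mapping a fixed-size read library against taxon references:
    counts for each sample are multinomial with probabilities proportional to
    abundance_i * length_i, so longer features soak up proportionally more
    reads.  Column sums equal ``library_size`` exactly; the expectation of
    TPM-normalizing the counts recovers the relative abundances as the
    library grows.
    """
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    lengths = np.broadcast_to(
        np.asarray(feature_lengths, dtype=float), (series.n_taxa,)
    )
    if (lengths <= 0).any():
        raise ValueError("feature lengths must be strictly positive")
    rng = np.random.default_rng(seed)
    counts = np.empty((series.n_taxa, series.n_time), dtype=np.int64)
    for j in range(series.n_time):
        weights = series.abundances[:, j] * lengths
        total = weights.sum()
        if total <= 0:
            raise ValueError(f"sample column {j} has zero total abundance")
        counts[:, j] = rng.multinomial(library_size, weights / total)
    return pd.DataFrame(counts, index=series.taxon_ids, columns=series.sample_ids())


@dataclass
class MetadataConfig:
    """Settings for the synthetic operational-parameter table.

    Defaults emulate a saline activated-sludge plant: salinity around 1.2%
    with a sustained 11-month dip, an annual temperature sinusoid, a mean
    cell residence time (MCRT) random walk, plus one covariate linearly
    coupled (on the z-score scale) to a chosen taxon with population
    correlation ``coupling``.
    """

    salinity_baseline: float = 1.2
    salinity_dip_start: int = 122
    salinity_dip_length: int = 11
    salinity_dip_drop: float = 0.5
    salinity_noise_sd: float = 0.05
    temperature_mean: float = 25.0
    temperature_amplitude: float = 5.0
    temperature_phase: float = 0.0
    temperature_noise_sd: float = 0.5
    mcrt_start: float = 10.0
    mcrt_step_sd: float = 0.4
    coupled_taxon: int = 0
    coupling: float = 0.7
    coupled_name: str = "coupled_covariate"


def simulate_metadata(
    series: CommunityTimeSeries,
    config: MetadataConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate an operational/physiochemical parameter table for a series.

    Returns a parameters-by-sample DataFrame aligned to the series time
    stamps.  The coupled covariate is built as
    ``coupling * z(taxon) + sqrt(1 - coupling^2) * N(0, 1)`` so its
    population Pearson correlation with the chosen taxon equals ``coupling``
    exactly in expectation.
    """
    cfg = config or MetadataConfig()
    if not -1.0 <= cfg.coupling <= 1.0:
        raise ValueError("coupling must be a correlation in [-1, 1]")
    n = series.n_time
    t = np.asarray(series.time_stamps, dtype=float)
    rng = np.random.default_rng(seed)

    salinity = np.full(n, cfg.salinity_baseline)
    dip = slice(cfg.salinity_dip_start, cfg.salinity_dip_start + cfg.salinity_dip_length)
    salinity[dip] -= cfg.salinity_dip_drop
    salinity += rng.normal(0.0, cfg.salinity_noise_sd, n)

    temperature = (
        cfg.temperature_mean
        + cfg.temperature_amplitude * np.sin(2 * np.pi * t / 12.0 + cfg.temperature_phase)
        + rng.normal(0.0, cfg.temperature_noise_sd, n)
    )

    mcrt = cfg.mcrt_start + np.cumsum(rng.normal(0.0, cfg.mcrt_step_sd, n))
    mcrt = np.maximum(mcrt, 1.0)

    x = series.abundances[cfg.coupled_taxon]
    sd = x.std()
    z = (x - x.mean()) / sd if sd > 0 else np.zeros(n)
    rho = cfg.coupling
    coupled = rho * z + np.sqrt(max(0.0, 1.0 - rho * rho)) * rng.normal(0.0, 1.0, n)

    return pd.DataFrame(
        {
            "salinity": salinity,
            "temperature": temperature,
            "mcrt": mcrt,
            cfg.coupled_name: coupled,
        },
        index=series.sample_ids(),
    ).T


def random_stable_params(
    n_taxa: int,
    seed: int,
    domain_labels: list[str] | None = None,
    seasonal_amplitude: float = 0.05,
    process_noise_sd: float = 0.05,
    interaction_density: float = 0.3,
    spectral_radius: float = 0.8,
) -> GLVParams:
    """Draw a random gLV parameter set kept inside a stability envelope.

    Self-limitation terms a_ii are uniform in [-0.2, -0.05]; off-diagonal
    coefficients are sparse Gaussians rescaled so the linearized map at the
    all-ones equilibrium, I + A, has spectral radius below
    ``spectral_radius`` < 1.  Growth rates are then set to r = -A @ 1 so the
    all-ones state is an equilibrium, which keeps trajectories bounded and
    strictly positive for the default noise level.
    """
    rng = np.random.default_rng(seed)
    a = np.zeros((n_taxa, n_taxa))
    mask = rng.random((n_taxa, n_taxa)) < interaction_density
    np.fill_diagonal(mask, False)
    a[mask] = rng.normal(0.0, 0.1, mask.sum())
    np.fill_diagonal(a, rng.uniform(-0.2, -0.05, n_taxa))
    # rescale off-diagonals until the linearization at x*=1 is contractive
    for _ in range(60):
        radius = np.abs(np.linalg.eigvals(np.eye(n_taxa) + a)).max()
        if radius < spectral_radius:
            break
        off = ~np.eye(n_taxa, dtype=bool)
        a[off] *= 0.8
    r = -a @ np.ones(n_taxa)
    return GLVParams(
        n_taxa=n_taxa,
        growth_rates=r,
        interaction_matrix=a,
        seasonal_amplitude=np.full(n_taxa, seasonal_amplitude),
        seasonal_phase=rng.uniform(0, 2 * np.pi, n_taxa),
        process_noise_sd=process_noise_sd,
        domain_labels=domain_labels or ["prokaryote"] * n_taxa,
    )


def linear_benchmark_system(
    seed: int,
    n_taxa: int = 8,
    n_steps: int = 200,
    noise_sd: float = 0.01,
    rho: float = 0.95,
) -> tuple[CommunityTimeSeries, np.ndarray]:
    """Linear stochastic benchmark x(t+1) = A x(t) + eps for recovery tests.

    A is ``rho`` times a seeded random orthogonal matrix, so the dynamics
    are stable yet persistent and the regression design stays well
    conditioned — identification error then reflects solver correctness
    rather than collinearity.  Returns the (standardizable) series and the
    true matrix A, which is exactly the system's Jacobian everywhere.
    """
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(n_taxa, n_taxa)))
    a = rho * q
    x = rng.normal(0.0, 1.0, n_taxa)
    states = [x]
    for _ in range(n_steps - 1):
        x = a @ x + rng.normal(0.0, noise_sd, n_taxa)
        states.append(x)
    series = CommunityTimeSeries(
        abundances=np.array(states).T,
        time_stamps=np.arange(n_steps),
        taxon_ids=[f"taxon_{i:02d}" for i in range(n_taxa)],
        standardized=True,
    )
    return series, a


#: Smallest |a_ij| counted as a true interaction in the benchmark recovery
#: protocol; entries below this are treated as structural zeros.
BENCHMARK_EFFECT_FLOOR = 0.05

#: (predator, prey) row indices of the designated exploitation pair in the
#: benchmark community (eukaryote E1 preying on prokaryote P1).
BENCHMARK_PREDATOR_PREY_PAIR = (4, 0)


def benchmark_glv_params(
    process_noise_sd: float = 0.05, seasonal_amplitude: float = 0.05
) -> GLVParams:
    """Fixed 8-taxon cross-domain benchmark community.

    Four prokaryotes (P1-P4), three eukaryotes (E1-E3) and one phage-like
    virus (V1) with a hand-designed interaction web: three predator-prey /
    exploitation pairs (E1-P1, E2-P2, E3-P4), one host-phage pair (V1-P3),
    one competitive pair (P1-P2) and one mutualistic pair (P3-P4).  Growth
    rates place the equilibrium at all-ones abundance; self-limitation -0.15
    keeps the linearized map well inside the unit circle.
    """
    a = np.zeros((8, 8))
    np.fill_diagonal(a, -0.15)
    P1, P2, P3, P4, E1, E2, E3, V1 = range(8)
    a[E1, P1], a[P1, E1] = +0.10, -0.12   # E1 preys on P1
    a[E2, P2], a[P2, E2] = +0.08, -0.10   # E2 preys on P2
    a[E3, P4], a[P4, E3] = +0.09, -0.08   # E3 preys on P4
    a[V1, P3], a[P3, V1] = +0.12, -0.10   # phage V1 exploits host P3
    a[P1, P2], a[P2, P1] = -0.06, -0.06   # competition
    a[P3, P4], a[P4, P3] = +0.05, +0.05   # mutualism
    r = -a @ np.ones(8)
    phases = 2 * np.pi * np.arange(8) / 8.0
    return GLVParams(
        n_taxa=8,
        growth_rates=r,
        interaction_matrix=a,
        seasonal_amplitude=np.full(8, seasonal_amplitude),
        seasonal_phase=phases,
        process_noise_sd=process_noise_sd,
        domain_labels=[
            "prokaryote", "prokaryote", "prokaryote", "prokaryote",
            "eukaryote", "eukaryote", "eukaryote", "virus",
        ],
    )
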