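"""Correlated synthetic EV characterization datasets.

Real multi-method EV comparisons are small (8-15 preparations) and their
factors are correlated — most notoriously the yield-purity trade-off, where
methods that recover more particles co-isolate more contaminating protein.
This module generates datasets with that structure so every pipeline stage
can be exercised, at any size, without laboratory data:

1. latent rows are drawn from a multivariate standard normal with the target
   correlation matrix (symmetric eigendecomposition factorization);
2. each latent column is pushed through its marginal's quantile function —
   Gaussian and lognormal in closed form, Poisson via the normal CDF followed
   by the discrete quantile (a Gaussian copula, so the correlation structure
   survives the change of marginals; discrete marginals attenuate the latent
   correlation slightly);
3. replicate-level multiplicative Gaussian noise with a chosen coefficient of
   variation emulates triplicate measurement scatter; replicates are averaged
   into the decision matrix exactly as bench triplicates would be.

Everything is reproducible bit-for-bit from the spec's seed. Two presets
mirror the validation shapes used for this kind of tool: 15 preparations x
11 physicochemical factors, and 8 preparations x 13 factors where
process-practicality criteria (time, cost) join the physicochemical ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, ValidationError
from .factors import DecisionMatrix, Direction, FactorSpec

__all__ = ["MarginalSpec", "SyntheticSpec", "generate_dataset", "preset_spec"]

_PSD_TOL = 1e-8
_MAX_RESAMPLE = 1000


@dataclass(frozen=True)
class MarginalSpec:
    """Marginal distribution + downstream factor metadata for one column.

    family ``gaussian`` uses (mean, sd); ``poisson`` uses rate; ``lognormal``
    uses (log_mean, log_sd) of the underlying normal. ``floor`` is an open
    lower truncation bound: rows whose draw lands at or below it are redrawn.
    When no explicit floor is given, one is derived from the direction
    (minimize needs values > 0; shifted_minimize needs values > -shift; a
    maximize column also needs values > 0 so its normalized column stays in
    (0, 1]).
    """

    name: str
    family: Literal["gaussian", "poisson", "lognormal"]
    mean: float | None = None
    sd: float | None = None
    rate: float | None = None
    log_mean: float | None = None
    log_sd: float | None = None
    direction: Direction = Direction.MAXIMIZE
    shift: float = 100.0
    units: str = ""
    floor: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", Direction.coerce(self.direction))
        if self.family == "gaussian":
            if self.mean is None or self.sd is None or not self.sd > 0:
                raise ConfigurationError(
                    f"marginal {self.name!r}: gaussian needs mean and sd > 0"
                )
            if (
                self.direction is Direction.MINIMIZE
                and self.mean - 6 * self.sd <= 0
                and self.floor is None
            ):
                raise ConfigurationError(
                    f"marginal {self.name!r}: gaussian for a minimize column "
                    "must satisfy mean - 6*sd > 0 or state an explicit floor"
                )
        elif self.family == "poisson":
            if self.rate is None or not self.rate > 0:
                raise ConfigurationError(
                    f"marginal {self.name!r}: poisson needs rate > 0"
                )
        elif self.family == "lognormal":
            if self.log_mean is None or self.log_sd is None or not self.log_sd > 0:
                raise ConfigurationError(
                    f"marginal {self.name!r}: lognormal needs log_mean and log_sd > 0"
                )
        else:
            raise ConfigurationError(
                f"marginal {self.name!r}: unknown family {self.family!r}"
            )

    @property
    def effective_floor(self) -> float | None:
        """Explicit floor, or the positivity bound the direction implies."""
        if self.floor is not None:
            return self.floor
        if self.direction is Direction.SHIFTED_MINIMIZE:
            return -self.shift
        if self.family == "lognormal":
            return None  # already strictly positive
        if self.direction in (Direction.MINIMIZE, Direction.MAXIMIZE):
            return 0.0
        return None

    def quantile(self, z: np.ndarray) -> np.ndarray:
        """Map latent standard-normal draws through this marginal."""
        if self.family == "gaussian":
            return self.mean + self.sd * z
        if self.family == "lognormal":
            return np.exp(self.log_mean + self.log_sd * z)
        # poisson: normal CDF -> discrete quantile keeps the copula ordering
        u = stats.norm.cdf(z)
        return stats.poisson.ppf(u, self.rate)

    def to_factor_spec(self, weight: float) -> FactorSpec:
        return FactorSpec(self.name, self.direction, self.shift, weight, self.units)


@dataclass
class SyntheticSpec:
    """Full recipe for one synthetic dataset.

    correlation is the latent (copula) correlation matrix over factors;
    noise_cv is the replicate-level coefficient of variation (0.05 = 5 %
    measurement scatter, a typical triplicate CV); replicates defaults to the
    bench-standard 3.
    """

    n_alternatives: int
    marginals: list[MarginalSpec]
    correlation: np.ndarray | None = None
    noise_cv: float = 0.05
    replicates: int = 3
    seed: int = 0
    alternative_prefix: str = "EV"

    def __post_init__(self) -> None:
        if self.n_alternatives < 2:
            raise ValidationError("need n_alternatives >= 2")
        if not self.marginals:
            raise ValidationError("need at least one marginal")
        names = [m.name for m in self.marginals]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate marginal names")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        k = len(self.marginals)
        if self.correlation is None:
            self.correlation = np.eye(k)
        r = np.asarray(self.correlation, dtype=float)
        if r.shape != (k, k):
            raise ValidationError(
                f"correlation must be {k}x{k}, got {r.shape}"
            )
        if not np.allclose(r, r.T, atol=1e-12):
            raise ValidationError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-12):
            raise ValidationError("correlation matrix must have unit diagonal")
        if np.any(np.abs(r) > 1 + 1e-12):
            raise ValidationError("correlation entries must lie in [-1, 1]")
        if np.linalg.eigvalsh(r).min() < -_PSD_TOL:
            raise ValidationError(
                "correlation matrix is not positive semi-definite"
            )
        self.correlation = r

    @property
    def factor_names(self) -> list[str]:
        return [m.name for m in self.marginals]


def _copula_rows(spec: SyntheticSpec, rng: np.random.Generator, n_rows: int) -> np.ndarray:
    """n_rows draws satisfying every marginal's floor; whole offending rows
    are redrawn so the correlation structure is never patched cell-wise."""
    r = spec.correlation
    eigval, eigvec = np.linalg.eigh(r)
    loading = eigvec @ np.diag(np.sqrt(np.clip(eigval, 0.0, None)))
    floors = [m.effective_floor for m in spec.marginals]

    def draw(n: int) -> np.ndarray:
        z = rng.standard_normal((n, len(spec.marginals))) @ loading.T
        x = np.empty_like(z)
        for j, m in enumerate(spec.marginals):
            x[:, j] = m.quantile(z[:, j])
        return x

    x = draw(n_rows)
    for _ in range(_MAX_RESAMPLE):
        bad = np.zeros(n_rows, dtype=bool)
        for j, f in enumerate(floors):
            if f is not None:
                bad |= x[:, j] <= f
        if not bad.any():
            return x
        x[bad] = draw(int(bad.sum()))
    raise ValidationError(
        f"marginals kept producing values at or below their floors after "
        f"{_MAX_RESAMPLE} resampling rounds; check marginal parameters"
    )


def generate_dataset(
    spec: SyntheticSpec, seed: int | None = None
) -> tuple[DecisionMatrix, pd.DataFrame]:
    """Generate (decision matrix, replicate-level long table) from a spec.

    The long table has columns (alternative, factor, replicate, value); the
    decision matrix holds the replicate means and equal factor weights. The
    optional ``seed`` argument overrides ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n, k = spec.n_alternatives, len(spec.marginals)
    base = _copula_rows(spec, rng, n)
    floors = [m.effective_floor for m in spec.marginals]

    # replicate noise: value * (1 + cv*eps); offending replicate rows redrawn
    # so replicate means respect the same floors the base values do
    reps = np.empty((spec.replicates, n, k))
    for t in range(spec.replicates):
        reps[t] = base * (1.0 + spec.noise_cv * rng.standard_normal((n, k)))
    for _ in range(_MAX_RESAMPLE):
        mean = reps.mean(axis=0)
        bad = np.zeros((n, k), dtype=bool)
        for j, f in enumerate(floors):
            if f is not None:
                bad[:, j] = (mean[:, j] <= f) | np.any(reps[:, :, j] <= f, axis=0)
        if not bad.any():
            break
        for t in range(spec.replicates):
            redraw = base * (1.0 + spec.noise_cv * rng.standard_normal((n, k)))
            reps[t][bad] = redraw[bad]
    else:
        raise ValidationError(
            "replicate noise kept violating marginal floors; lower noise_cv"
        )

    alts = [f"{spec.alternative_prefix}{i + 1:02d}" for i in range(n)]
    names = spec.factor_names
    long_rows = {
        "alternative": np.repeat(alts, k * spec.replicates),
        "factor": np.tile(np.repeat(names, spec.replicates), n),
        "replicate": np.tile(np.arange(1, spec.replicates + 1), n * k),
        "value": np.stack(
            [reps[t] for t in range(spec.replicates)], axis=-1
        ).reshape(-1),
    }
    long_table = pd.DataFrame(long_rows)

    values = pd.DataFrame(reps.mean(axis=0), index=alts, columns=names)
    weight = 1.0 / k
    factor_specs = [m.to_factor_spec(weight) for m in spec.marginals]
    return DecisionMatrix(values, factor_specs), long_table


# ---------------------------------------------------------------------------
# presets

def _base_marginals() -> list[MarginalSpec]:
    g, p, ln = "gaussian", "poisson", "lognormal"
    MIN, MAX, SHIFT = Direction.MINIMIZE, Direction.MAXIMIZE, Direction.SHIFTED_MINIMIZE
    return [
        MarginalSpec("mean_size_nm", g, mean=155, sd=15, direction=MIN, units="nm"),
        MarginalSpec("zeta_potential_mV", g, mean=-25, sd=8, direction=SHIFT,
                     shift=100, units="mV"),
        MarginalSpec("particle_recovery_pct", g, mean=45, sd=12, direction=MAX,
                     units="%", floor=1.0),
        MarginalSpec("particle_concentration_e9_per_mL", p, rate=100,
                     direction=MAX, units="1e9 particles/mL"),
        MarginalSpec("protein_purity_particles_per_ug", ln,
                     log_mean=math.log(6e10), log_sd=0.8, direction=MAX,
                     units="particles/ug protein"),
        MarginalSpec("nucleic_acid_purity_particles_per_ng", ln,
                     log_mean=math.log(3e11), log_sd=0.7, direction=MAX,
                     units="particles/ng NA"),
        MarginalSpec("protein_concentration_ug_per_mL", g, mean=250, sd=60,
                     direction=MAX, units="ug/mL", floor=1.0),
        MarginalSpec("nucleic_acid_concentration_ng_per_uL", g, mean=55, sd=15,
                     direction=MAX, units="ng/uL", floor=1.0),
        MarginalSpec("tpc_mg_gae_per_g", g, mean=42, sd=6, direction=MIN,
                     units="mg GAE/g"),
        MarginalSpec("tfc_mg_re_per_g", g, mean=30, sd=7, direction=MAX,
                     units="mg RE/g", floor=0.5),
        MarginalSpec("dpph_scavenging_pct", g, mean=60, sd=12, direction=MAX,
                     units="%", floor=1.0),
    ]


def _preset_correlation(names: list[str], entries: dict[tuple[str, str], float]) -> np.ndarray:
    k = len(names)
    r = np.eye(k)
    idx = {n: i for i, n in enumerate(names)}
    for (a, b), v in entries.items():
        r[idx[a], idx[b]] = r[idx[b], idx[a]] = v
    return r


#: planted latent correlations shared by both presets; the negative
#: recovery <-> purity entries are the yield-purity trade-off
_TRADEOFF_ENTRIES = {
    ("particle_recovery_pct", "protein_purity_particles_per_ug"): -0.60,
    ("particle_recovery_pct", "nucleic_acid_purity_particles_per_ng"): -0.50,
    ("particle_recovery_pct", "particle_concentration_e9_per_mL"): 0.60,
    ("particle_concentration_e9_per_mL", "protein_purity_particles_per_ug"): -0.30,
    ("particle_concentration_e9_per_mL", "nucleic_acid_purity_particles_per_ng"): -0.30,
    ("protein_purity_particles_per_ug", "nucleic_acid_purity_particles_per_ng"): 0.40,
    ("tpc_mg_gae_per_g", "tfc_mg_re_per_g"): 0.50,
    ("tfc_mg_re_per_g", "dpph_scavenging_pct"): 0.60,
    ("tpc_mg_gae_per_g", "dpph_scavenging_pct"): 0.40,
}


def preset_spec(name: str, seed: int = 0) -> SyntheticSpec:
    """Named dataset recipes: ``ev15x11`` (15 preparations x 11
    physicochemical factors) and ``ev8x13`` (8 preparations x the same 11
    plus isolation time and cost as minimize criteria)."""
    if name == "ev15x11":
        marginals = _base_marginals()
        return SyntheticSpec(
            n_alternatives=15,
            marginals=marginals,
            correlation=_preset_correlation(
                [m.name for m in marginals], _TRADEOFF_ENTRIES
            ),
            seed=seed,
        )
    if name == "ev8x13":
        marginals = _base_marginals() + [
            MarginalSpec("isolation_time_h", "gaussian", mean=12, sd=1.8,
                         direction=Direction.MINIMIZE, units="h"),
            MarginalSpec("cost_usd_per_prep", "gaussian", mean=150, sd=20,
                         direction=Direction.MINIMIZE, units="USD"),
        ]
        entries = dict(_TRADEOFF_ENTRIES)
        entries[("isolation_time_h", "cost_usd_per_prep")] = 0.50
        return SyntheticSpec(
            n_alternatives=8,
            marginals=marginals,
            correlation=_preset_correlation([m.name for m in marginals], entries),
            seed=seed,
        )
    raise ConfigurationError(
        f"unknown preset {name!r}; available: 'ev15x11', 'ev8x13'"
    )
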