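"""Competitive-assay statistics: %-of-control normalisation and Dunnett tests.

The binding readout is expressed as percent of the vehicle (DMSO) control,
and each drug dose is compared to that control with a two-tailed Dunnett
many-to-one procedure, which controls the family-wise error across the k
dose groups.

The adjusted p-value is computed from the k-variate equicorrelated t
distribution: writing the many-to-one t statistics as

    T_i = (lam_i * Z0 + sqrt(1 - lam_i**2) * Z_i) / U,

with Z0, Z_i independent standard normals, U = S/sigma the pooled-SD
factor (sqrt(chi2_df / df)), and lam_i = sqrt(n_i / (n_i + n0)) — the
n_i-weighted generalisation of the equal-n correlation 1/2 — the
family-wise p is P(max_i |T_i| >= |t_obs|), evaluated by Gauss-Hermite x
chi quadrature in complement form so extreme tails keep full relative
accuracy. A seeded Monte Carlo estimator of the same probability serves
as a cross-check.

Two data modes exist. With replicates (or per-group summaries plus a
control summary) the standard pooled-variance Dunnett is used. In
*fixed-reference* mode the control is treated as the exact constant it
was normalised to (100%), with variance pooled across the treatment
groups only — the mode needed when a publication prints treatment
mean ± SD but no control SD; there lam_i = 0 (no shared control noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from numpy.polynomial.legendre import leggauss
from scipy import stats as sps
from scipy.optimize import brentq
from scipy.special import ndtr

__all__ = [
    "AssayTable",
    "DunnettResult",
    "percent_of_control",
    "dunnett_test",
    "dunnett_sf",
    "dunnett_sf_mc",
    "dunnett_critical_value",
    "simulate_assay",
]


@dataclass
class AssayTable:
    """Dose groups with replicate values or (mean, sd, n) summaries.

    ``groups`` preserves dose order; ``control`` names the reference group
    when one exists (fixed-reference analyses need none).
    """

    groups: list[str]
    summaries: dict[str, tuple[float, float, int]]
    replicates: dict[str, np.ndarray] | None = None
    control: str | None = None

    def __post_init__(self) -> None:
        for label in self.groups:
            mean, sd, n = self.summaries[label]
            if n < 1:
                raise ValueError(f"group {label!r}: n must be >= 1")
            if sd < 0:
                raise ValueError(f"group {label!r}: sd must be >= 0")
        if self.control is not None and self.control not in self.groups:
            raise ValueError(f"control group {self.control!r} not in table")

    @classmethod
    def from_replicates(
        cls, data: dict[str, np.ndarray], control: str | None = None
    ) -> "AssayTable":
        reps = {k: np.asarray(v, dtype=float) for k, v in data.items()}
        summaries = {
            k: (float(v.mean()), float(v.std(ddof=1)) if len(v) > 1 else 0.0, len(v))
            for k, v in reps.items()
        }
        return cls(
            groups=list(data), summaries=summaries, replicates=reps, control=control
        )

    @classmethod
    def from_summaries(
        cls,
        data: dict[str, tuple[float, float, int]],
        control: str | None = None,
    ) -> "AssayTable":
        return cls(groups=list(data), summaries=dict(data), control=control)

    def treatment_groups(self) -> list[str]:
        return [g for g in self.groups if g != self.control]


@dataclass(frozen=True)
class DunnettResult:
    """Per-comparison t statistics and family-wise adjusted p-values."""

    groups: tuple[str, ...]
    t: np.ndarray
    p_adjusted: np.ndarray
    p_unadjusted: np.ndarray
    df: int
    k: int
    lambdas: np.ndarray

    def as_dict(self) -> dict[str, dict[str, float]]:
        return {
            g: {
                "t": float(self.t[i]),
                "p_adjusted": float(self.p_adjusted[i]),
                "p_unadjusted": float(self.p_unadjusted[i]),
            }
            for i, g in enumerate(self.groups)
        }


def percent_of_control(
    raw: dict[str, np.ndarray], control: str
) -> AssayTable:
    """Scale raw counts to percent of the control-group mean.

    Every replicate is multiplied by ``100 / mean(control)``, so the
    control group's own mean becomes exactly 100.
    """
    ctrl = np.asarray(raw[control], dtype=float)
    m = ctrl.mean()
    if m <= 0:
        raise ValueError(f"control mean must be positive, got {m}")
    scaled = {k: np.asarray(v, dtype=float) * (100.0 / m) for k, v in raw.items()}
    return AssayTable.from_replicates(scaled, control=control)


# ---------------------------------------------------------------------------
# Equicorrelated multivariate-t tail probabilities

_N_CHI_NODES = 128
_N_HERMITE_NODES = 96


def _chi_nodes(df: int) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature nodes/weights for U = sqrt(chi2_df / df), via its CDF.

    Composite rule on the probability scale: log-spaced Gauss-Legendre on
    the lower tail (which dominates extreme t tails) plus a linear panel
    on the bulk, so small exceedance probabilities keep relative accuracy.
    """
    x, w = leggauss(_N_CHI_NODES)
    # lower tail, p = exp(y) on [1e-22, 1/2]
    ylo, yhi = np.log(1e-22), np.log(0.5)
    y = 0.5 * (yhi - ylo) * (x + 1.0) + ylo
    p_tail = np.exp(y)
    w_tail = 0.5 * (yhi - ylo) * w * p_tail  # dp = p dy
    # bulk, p on [1/2, 1]
    p_bulk = 0.25 * (x + 1.0) + 0.5
    w_bulk = 0.25 * w
    p = np.concatenate([p_tail, p_bulk])
    wt = np.concatenate([w_tail, w_bulk])
    u = np.sqrt(sps.chi2.ppf(p, df) / df)
    return u, wt


def dunnett_sf(q: float, df: int, lambdas: np.ndarray) -> float:
    """P(max_i |T_i| >= q) for the many-to-one t statistics (two-sided).

    ``lambdas`` carries one correlation loading per comparison
    (sqrt(n_i / (n_i + n0)); zeros in fixed-reference mode). Evaluated in
    complement form (log1p/expm1), so values far below machine epsilon of
    1 remain accurate.
    """
    q = float(abs(q))
    lam = np.asarray(lambdas, dtype=float)
    if np.any((lam < 0) | (lam >= 1)):
        raise ValueError("lambdas must lie in [0, 1)")
    # Far in the tail the union bound k * P(|t_df| > q) is asymptotically
    # exact (joint exceedances decay like q**(-2*df) vs q**(-df)) and the
    # marginal t tail is computed to full relative accuracy by scipy;
    # quadrature below its own resolution floor would round to 0 instead.
    bonferroni = float(2.0 * lam.size * sps.t.sf(q, df))
    if bonferroni < 1e-8:
        return bonferroni
    u, wu = _chi_nodes(df)
    if np.any(lam > 0):
        z, wz = hermegauss(_N_HERMITE_NODES)
        wz = wz / np.sqrt(2.0 * np.pi)
    else:
        z = np.zeros(1)
        wz = np.ones(1)
    s = np.sqrt(1.0 - lam**2)
    # shape (n_u, n_z, k)
    qu = q * u[:, None, None]
    lz = lam[None, None, :] * z[None, :, None]
    upper = (qu - lz) / s[None, None, :]
    lower = (qu + lz) / s[None, None, :]
    # log P(|T_i| <= q | u, z) = log1p(-(Q(upper) + Q(lower)))
    tail_sum = np.clip(
        (1.0 - ndtr(upper)) + (1.0 - ndtr(lower)), 0.0, 1.0 - 1e-16
    )
    log_all_in = np.log1p(-tail_sum).sum(axis=2)
    complement = -np.expm1(log_all_in)  # P(any |T_i| > q | u, z)
    val = float(wu @ complement @ wz)
    return min(max(val, 0.0), 1.0)


def dunnett_sf_mc(
    q: float,
    df: int,
    lambdas: np.ndarray,
    n_draws: int = 200_000,
    rng: np.random.Generator | int | None = 0,
) -> float:
    """Monte Carlo estimate of :func:`dunnett_sf` (seeded cross-check)."""
    rng = np.random.default_rng(rng)
    lam = np.asarray(lambdas, dtype=float)
    k = lam.size
    z0 = rng.standard_normal(n_draws)
    z = rng.standard_normal((n_draws, k))
    u = np.sqrt(rng.chisquare(df, n_draws) / df)
    T = (lam * z0[:, None] + np.sqrt(1 - lam**2) * z) / u[:, None]
    return float((np.abs(T).max(axis=1) >= abs(q)).mean())


def dunnett_critical_value(
    alpha: float, df: int, lambdas: np.ndarray
) -> float:
    """Two-sided critical value q with P(max_i |T_i| >= q) = alpha."""
    return float(
        brentq(lambda q: dunnett_sf(q, df, lambdas) - alpha, 1e-6, 50.0, xtol=1e-10)
    )


# ---------------------------------------------------------------------------
# The test itself


def dunnett_test(
    table: AssayTable, fixed_reference: float | None = None
) -> DunnettResult:
    """Two-tailed Dunnett many-to-one comparison of dose groups to control.

    With ``fixed_reference`` set (e.g. 100.0 for %-of-control data whose
    control SD is unknown), every group in the table is compared to that
    constant, the variance is pooled across those groups, and the
    statistics are independent given the pooled SD (lambda = 0).
    Otherwise the table's ``control`` group supplies the reference mean
    and joins the variance pool, and lambda_i = sqrt(n_i / (n_i + n0)).
    """
    if fixed_reference is not None:
        labels = list(table.groups)
        if not labels:
            raise ValueError("no treatment groups to compare")
        stats = [table.summaries[g] for g in labels]
        ref_mean = float(fixed_reference)
        n0 = None
    else:
        if table.control is None:
            raise ValueError("table has no control group; use fixed_reference")
        labels = table.treatment_groups()
        if not labels:
            raise ValueError("no treatment groups to compare")
        stats = [table.summaries[g] for g in labels]
        m0, sd0, n0 = table.summaries[table.control]
        ref_mean = m0

    means = np.array([s[0] for s in stats])
    sds = np.array([s[1] for s in stats])
    ns = np.array([s[2] for s in stats])
    if np.any(ns < 2):
        raise ValueError("every pooled group needs n >= 2 replicates")

    ss = ((ns - 1) * sds**2).sum()
    df = int((ns - 1).sum())
    if n0 is not None:
        if n0 < 2:
            raise ValueError("control group needs n >= 2 replicates")
        ss += (n0 - 1) * sd0**2
        df += n0 - 1
    if df < 1:
        raise ValueError("no degrees of freedom to estimate variance")
    s_pooled = np.sqrt(ss / df)
    if s_pooled == 0:
        raise ValueError("pooled variance is zero; t statistics undefined")

    if n0 is None:
        se = s_pooled * np.sqrt(1.0 / ns)
        lambdas = np.zeros(len(ns))
    else:
        se = s_pooled * np.sqrt(1.0 / ns + 1.0 / n0)
        lambdas = np.sqrt(ns / (ns + n0))

    t = (means - ref_mean) / se
    p_adj = np.array([dunnett_sf(abs(ti), df, lambdas) for ti in t])
    p_raw = 2.0 * sps.t.sf(np.abs(t), df)
    return DunnettResult(
        groups=tuple(labels),
        t=t,
        p_adjusted=p_adj,
        p_unadjusted=p_raw,
        df=df,
        k=len(labels),
        lambdas=lambdas,
    )


# ---------------------------------------------------------------------------
# Synthetic assay tables


def simulate_assay(
    effects: dict[str, float],
    noise_sd: float,
    replicates: int = 4,
    seed: int | np.random.Generator = 0,
    control_mean: float = 100.0,
    control_label: str = "control",
) -> AssayTable:
    """Gaussian replicate counts around control_mean x effect size.

    ``effects`` maps group label -> multiplicative effect (1.0 = null);
    ``noise_sd`` is the replicate SD on the %-of-control scale. A control
    group with effect 1.0 is always included. Fully determined by the seed.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates per group")
    rng = np.random.default_rng(seed)
    data: dict[str, np.ndarray] = {
        control_label: control_mean + noise_sd * rng.standard_normal(replicates)
    }
    for label, eff in effects.items():
        data[label] = control_mean * eff + noise_sd * rng.standard_normal(replicates)
    return AssayTable.from_replicates(data, control=control_label)
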