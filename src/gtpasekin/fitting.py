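"""Rate-constant estimation from traces and time courses.

The analysis chain mirrors the standard stopped-flow workflow for small
GTPases:

1. each association trace is fit to ``F(t) = F0 + A*(1 - exp(-k_obs*t))``
   to obtain the observed pseudo-first-order rate ``k_obs``;
2. ``k_obs`` is regressed on protein concentration — the slope is the
   second-order association rate constant ``k_on`` (µM^-1 s^-1) and the
   intercept estimates ``k_off``;
3. dissociation chases are fit to ``F(t) = F_inf + A*exp(-k_off*t)``;
4. the dissociation constant is ``K_d = k_off / k_on`` (µM);
5. HPLC GTP-content courses are fit to ``f(t) = A*exp(-k_cat*t)``.

Standard errors come from the curvature (covariance) of the nonlinear
least-squares objective at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import (
    InvalidInputError,
    ModeMismatchError,
    UndefinedAffinityError,
)
from .synthetic import FluorescenceTrace, HydrolysisTimeCourse

#: Reason code stored when association was too weak/fast to measure.
NO_BINDING_OBSERVED = "no_binding_observed"

_REL_FLAT = 1e-9  # amplitude below this fraction of signal scale = flat trace


@dataclass(frozen=True)
class ExponentialFit:
    """Result of a single-exponential fit.

    ``rate`` is k_obs for association traces, k_off for dissociation
    chases, and k_cat for hydrolysis courses. ``converged`` is False for
    degenerate inputs (flat signal, zero rate) — the reported numbers are
    then best-effort and should not be propagated.
    """

    rate: float
    amplitude: float
    offset: float
    rate_stderr: float
    converged: bool
    residual_rms: float


@dataclass(frozen=True)
class KobsSeries:
    """Observed rates across a protein-concentration ladder."""

    protein_conc_uM: np.ndarray
    kobs: np.ndarray
    kobs_stderr: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.protein_conc_uM, dtype=float)
        k = np.asarray(self.kobs, dtype=float)
        se = np.asarray(self.kobs_stderr, dtype=float)
        object.__setattr__(self, "protein_conc_uM", c)
        object.__setattr__(self, "kobs", k)
        object.__setattr__(self, "kobs_stderr", se)
        if not (c.size == k.size == se.size) or c.size < 3:
            raise InvalidInputError("need >= 3 matched (conc, kobs, stderr) points")
        if np.any(c <= 0):
            raise InvalidInputError("protein concentrations must be positive")
        if len(np.unique(c)) != c.size:
            raise InvalidInputError("protein concentrations must be distinct")


@dataclass(frozen=True)
class LinearFit:
    """Ordinary least-squares line of k_obs against protein concentration.

    ``slope`` is the k_on estimate (µM^-1 s^-1); ``intercept`` should be
    consistent with the independently measured k_off.
    """

    slope: float
    intercept: float
    slope_stderr: float
    r_squared: float
    flagged: bool = False


@dataclass(frozen=True)
class NucleotideKinetics:
    """Per-variant, per-nucleotide kinetic constants.

    ``k_on`` may be None when binding was not observable (recorded via
    ``reason``); an absent k_on forces an absent K_d. When both rates are
    present the stored K_d is exactly ``k_off/k_on``.
    """

    variant_label: str
    nucleotide: str
    k_off: float
    k_on: float | None = None
    K_d: float | None = None
    reason: str | None = None

    def __post_init__(self) -> None:
        if self.nucleotide not in ("GDP", "GppNHp"):
            raise InvalidInputError("nucleotide must be 'GDP' or 'GppNHp'")
        if self.k_on is None:
            if self.K_d is not None:
                raise InvalidInputError("K_d must be absent when k_on is absent")
        else:
            if self.k_on <= 0:
                raise InvalidInputError("k_on must be positive when present")
            expected = self.k_off / self.k_on
            if self.K_d is None:
                object.__setattr__(self, "K_d", expected)
            elif expected != 0 and abs(self.K_d - expected) > 1e-12 * abs(expected):
                raise InvalidInputError("stored K_d must equal k_off/k_on")

    @classmethod
    def from_rates(
        cls, variant_label: str, nucleotide: str,
        k_on: float | None, k_off: float, reason: str | None = None,
    ) -> "NucleotideKinetics":
        if k_on is None and reason is None:
            reason = NO_BINDING_OBSERVED
        return cls(variant_label=variant_label, nucleotide=nucleotide,
                   k_off=k_off, k_on=k_on, reason=reason)


def _fit_curve(model, t, y, p0, bounds) -> tuple[np.ndarray, np.ndarray, bool]:
    try:
        popt, pcov = optimize.curve_fit(
            model, t, y, p0=p0, bounds=bounds, maxfev=20_000, method="trf",
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        ok = np.all(np.isfinite(popt)) and np.all(np.isfinite(np.diag(pcov)))
        return popt, pcov, bool(ok)
    except (RuntimeError, optimize.OptimizeWarning, ValueError):
        return np.array(p0, float), np.full((len(p0), len(p0)), np.nan), False


def _degenerate_fit(y: np.ndarray) -> ExponentialFit:
    return ExponentialFit(
        rate=0.0, amplitude=float(np.ptp(y)), offset=float(np.mean(y)),
        rate_stderr=float("nan"), converged=False,
        residual_rms=float(np.std(y)),
    )


def _init_rate(t: np.ndarray, y_decaying: np.ndarray) -> float:
    """Crude rate estimate from the time at which the decaying component halves."""
    y0, y1 = y_decaying[0], y_decaying[-1]
    half = y1 + 0.5 * (y0 - y1)
    idx = np.argmin(np.abs(y_decaying - half))
    t_half = t[idx] if t[idx] > 0 else t[1]
    return float(np.log(2.0) / t_half)


def fit_exponential_association(trace: FluorescenceTrace) -> ExponentialFit:
    """Fit ``F(t) = F0 + A*(1 - exp(-k*t))`` to an association trace.

    Raises :class:`ModeMismatchError` for dissociation-mode traces or
    signals that clearly decrease. A flat trace returns a fit with
    ``converged=False`` rather than raising.
    """
    if trace.mode == "dissociation":
        raise ModeMismatchError("trace is dissociation-mode; use fit_exponential_decay")
    t, y = trace.time_s, trace.signal_au
    scale = max(np.max(np.abs(y)), 1.0)
    n_edge = max(3, len(y) // 10)
    rise = float(np.mean(y[-n_edge:]) - np.mean(y[:n_edge]))
    if abs(rise) <= _REL_FLAT * scale and np.ptp(y) <= 1e-6 * scale:
        return _degenerate_fit(y)
    if rise < 0:
        raise ModeMismatchError("signal decreases; not an association trace")

    f0 = float(np.min(y[:n_edge]))
    amp = float(np.mean(y[-n_edge:]) - f0)
    k0 = _init_rate(t, np.mean(y[-n_edge:]) - y)  # decaying component A*exp(-kt)
    model = lambda tt, f0_, a_, k_: f0_ + a_ * (1.0 - np.exp(-k_ * tt))
    popt, pcov, ok = _fit_curve(
        model, t, y, p0=[f0, amp, max(k0, 1e-12)],
        bounds=([-np.inf, 0.0, 1e-15], [np.inf, np.inf, np.inf]),
    )
    resid = y - model(t, *popt)
    return ExponentialFit(
        rate=float(popt[2]), amplitude=float(popt[1]), offset=float(popt[0]),
        rate_stderr=float(np.sqrt(pcov[2, 2])) if ok else float("nan"),
        converged=bool(ok and popt[2] > 0 and popt[1] > _REL_FLAT * scale),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def fit_exponential_decay(trace: FluorescenceTrace) -> ExponentialFit:
    """Fit ``F(t) = F_inf + A*exp(-k*t)`` to a dissociation chase trace."""
    if trace.mode == "association":
        raise ModeMismatchError("trace is association-mode; use fit_exponential_association")
    t, y = trace.time_s, trace.signal_au
    scale = max(np.max(np.abs(y)), 1.0)
    n_edge = max(3, len(y) // 10)
    drop = float(np.mean(y[:n_edge]) - np.mean(y[-n_edge:]))
    if abs(drop) <= _REL_FLAT * scale and np.ptp(y) <= 1e-6 * scale:
        return _degenerate_fit(y)
    if drop < 0:
        raise ModeMismatchError("signal increases; not a dissociation trace")

    f_inf = float(np.mean(y[-n_edge:]))
    amp = float(np.mean(y[:n_edge]) - f_inf)
    k0 = _init_rate(t, y - f_inf)
    model = lambda tt, finf_, a_, k_: finf_ + a_ * np.exp(-k_ * tt)
    popt, pcov, ok = _fit_curve(
        model, t, y, p0=[f_inf, amp, max(k0, 1e-12)],
        bounds=([-np.inf, 0.0, 1e-15], [np.inf, np.inf, np.inf]),
    )
    resid = y - model(t, *popt)
    return ExponentialFit(
        rate=float(popt[2]), amplitude=float(popt[1]), offset=float(popt[0]),
        rate_stderr=float(np.sqrt(pcov[2, 2])) if ok else float("nan"),
        converged=bool(ok and popt[2] > 0 and popt[1] > _REL_FLAT * scale),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def fit_kobs_ladder(traces: list[FluorescenceTrace]) -> KobsSeries:
    """Fit every trace of a concentration ladder and collect k_obs."""
    concs, rates, errs = [], [], []
    for tr in traces:
        if tr.protein_conc_uM is None:
            raise InvalidInputError("ladder traces need protein_conc_uM metadata")
        fit = fit_exponential_association(tr)
        concs.append(tr.protein_conc_uM)
        rates.append(fit.rate)
        errs.append(fit.rate_stderr)
    return KobsSeries(np.array(concs), np.array(rates), np.array(errs))


def fit_kon(series: KobsSeries, strict: bool = False) -> LinearFit:
    """OLS regression of k_obs on protein concentration (free intercept).

    The slope estimates k_on; a negative slope is physically meaningless
    and is flagged (or raised when ``strict``).
    """
    res = stats.linregress(series.protein_conc_uM, series.kobs)
    flagged = res.slope < 0
    if flagged and strict:
        raise InvalidInputError(f"negative fitted k_on slope ({res.slope:.3g})")
    return LinearFit(
        slope=float(res.slope), intercept=float(res.intercept),
        slope_stderr=float(res.stderr), r_squared=float(res.rvalue**2),
        flagged=bool(flagged),
    )


def compute_kd(k_off: float, k_on: float) -> float:
    """Dissociation constant K_d = k_off / k_on (µM).

    Raises :class:`UndefinedAffinityError` when ``k_on <= 0`` — the case
    recorded as "no binding observed" experimentally.
    """
    if k_on <= 0:
        raise UndefinedAffinityError("K_d undefined: no association rate (k_on <= 0)")
    if k_off < 0:
        raise InvalidInputError("k_off must be nonnegative")
    return k_off / k_on


def fit_kcat(tc: HydrolysisTimeCourse) -> ExponentialFit:
    """Fit first-order GTP decay ``f(t) = A*exp(-k_cat*t)`` to an HPLC course.

    A course with no decay (all fractions equal, e.g. k_cat = 0) returns
    ``converged=False`` with rate 0.
    """
    t, f = tc.time_s, tc.gtp_fraction
    if np.ptp(f) <= 1e-12:
        return ExponentialFit(
            rate=0.0, amplitude=float(f[0]), offset=0.0,
            rate_stderr=float("nan"), converged=False, residual_rms=0.0,
        )
    k0 = _init_rate(t, f)
    model = lambda tt, a_, k_: a_ * np.exp(-k_ * tt)
    popt, pcov, ok = _fit_curve(
        model, t, f, p0=[float(f[0]) or 1.0, max(k0, 1e-12)],
        bounds=([0.0, 1e-15], [np.inf, np.inf]),
    )
    resid = f - model(t, *popt)
    return ExponentialFit(
        rate=float(popt[1]), amplitude=float(popt[0]), offset=0.0,
        rate_stderr=float(np.sqrt(pcov[1, 1])) if ok else float("nan"),
        converged=bool(ok and popt[1] > 0),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


TABLE_COLUMNS = [
    "variant", "nucleotide", "k_on_per_uM_s", "k_off_per_s", "Kd_uM", "kcat_per_s",
]


@dataclass(frozen=True)
class KineticsTable:
    """Summary table of per-variant constants plus derived fold-changes.

    ``fold_changes`` maps descriptive keys (e.g. ``kon_Q70L_over_WT_GDP``)
    to ratios computed purely from table entries.
    """

    table: pd.DataFrame
    fold_changes: dict[str, float] = field(default_factory=dict)


def build_kinetics_table(
    entries: list[NucleotideKinetics],
    k_cat_by_variant: dict[str, float] | None = None,
    reference_variant: str = "WT",
    fold_changes: bool | str = "auto",
    reported_kd: dict[tuple[str, str], float] | None = None,
) -> KineticsTable:
    """Assemble the kinetics summary table and its fold-change block.

    Fold-changes are quotients of table entries only: mutant/reference
    ratios of k_on, k_off and K_d per nucleotide, per-variant GDP/GppNHp
    k_off and K_d ratios, and the exchange/hydrolysis ratio
    k_off(GDP)/k_cat. With ``fold_changes="auto"`` the block is simply
    omitted when the reference variant is absent; ``True`` raises instead.

    ``reported_kd`` maps ``(variant, nucleotide)`` to an independently
    reported affinity (e.g. a source's own table, computed before its
    rates were rounded for print). When supplied it is carried as a
    ``Kd_reported_uM`` column and preferred for the K_d ratios, since
    ratios of re-derived K_d values compound the rounding of both rates.
    """
    if not entries:
        raise InvalidInputError("need at least one kinetics entry")
    k_cat_by_variant = k_cat_by_variant or {}
    reported_kd = reported_kd or {}
    rows = [
        {
            "variant": e.variant_label,
            "nucleotide": e.nucleotide,
            "k_on_per_uM_s": e.k_on,
            "k_off_per_s": e.k_off,
            "Kd_uM": e.K_d,
            "kcat_per_s": k_cat_by_variant.get(e.variant_label),
        }
        for e in entries
    ]
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    if reported_kd:
        table["Kd_reported_uM"] = [
            reported_kd.get((e.variant_label, e.nucleotide)) for e in entries
        ]

    def kd_of(entry: NucleotideKinetics) -> float | None:
        return reported_kd.get((entry.variant_label, entry.nucleotide), entry.K_d)

    by_key = {(e.variant_label, e.nucleotide): e for e in entries}
    variants = list(dict.fromkeys(e.variant_label for e in entries))
    have_ref = reference_variant in variants
    if fold_changes is True and not have_ref:
        raise InvalidInputError(
            f"fold-changes requested but reference variant {reference_variant!r} is missing"
        )
    fc: dict[str, float] = {}
    if fold_changes in (True, "auto") and have_ref:
        for v in variants:
            if v == reference_variant:
                continue
            for nuc in ("GDP", "GppNHp"):
                mut, ref = by_key.get((v, nuc)), by_key.get((reference_variant, nuc))
                if mut is None or ref is None:
                    continue
                if mut.k_on is not None and ref.k_on is not None:
                    fc[f"kon_{v}_over_{reference_variant}_{nuc}"] = mut.k_on / ref.k_on
                fc[f"koff_{v}_over_{reference_variant}_{nuc}"] = mut.k_off / ref.k_off
                kd_mut, kd_ref = kd_of(mut), kd_of(ref)
                if kd_mut is not None and kd_ref is not None:
                    fc[f"Kd_{v}_over_{reference_variant}_{nuc}"] = kd_mut / kd_ref
        for v in variants:
            gdp, gnp = by_key.get((v, "GDP")), by_key.get((v, "GppNHp"))
            if gdp is not None and gnp is not None and gnp.k_off > 0:
                fc[f"koff_GDP_over_GppNHp_{v}"] = gdp.k_off / gnp.k_off
                kd_gdp, kd_gnp = kd_of(gdp), kd_of(gnp)
                if kd_gdp is not None and kd_gnp is not None and kd_gnp > 0:
                    fc[f"Kd_GDP_over_GppNHp_{v}"] = kd_gdp / kd_gnp
            kcat = k_cat_by_variant.get(v)
            if gdp is not None and kcat:
                fc[f"koff_GDP_over_kcat_{v}"] = gdp.k_off / kcat
    return KineticsTable(table=table, fold_changes=fc)
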