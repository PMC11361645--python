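"""Three-state nucleotide cycle: free / GDP-bound / GTP-bound protein.

The scheme (pools of free GTP and GDP clamped, protein dilute):

    F  --k_on_GDP*[GDP]-->  D      D --k_off_GDP--> F
    F  --k_on_GTP*[GTP]-->  T      T --k_off_GTP--> F
    T  --k_cat-->           D      (hydrolysis; product GDP stays bound)

Because the pools are clamped the system is linear in the three state
fractions and the steady state is closed-form:

    T/F = k_on_GTP*[GTP] / (k_off_GTP + k_cat)
    D/F = (k_on_GDP*[GDP] + k_cat*(T/F)) / k_off_GDP

normalized so f_free + f_GDP + f_GTP = 1. A GTPase with fast intrinsic
exchange (large k_off_GDP) and slow hydrolysis (small k_cat) accumulates
GTP-loaded without GEF assistance — the non-classical regime; classical
GTPases sit GDP-loaded at rest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .errors import InvalidInputError

#: Default clamped cellular nucleotide pools (µM), roughly 10:1 GTP:GDP.
DEFAULT_GTP_UM = 500.0
DEFAULT_GDP_UM = 50.0

#: Classification thresholds: exchange/hydrolysis ratio and steady-state
#: GTP occupancy that operationalize "accumulates GTP-loaded".
DEFAULT_R1_THRESHOLD = 5.0
DEFAULT_FGTP_THRESHOLD = 0.5

NON_CLASSICAL = "non_classical_GTP_loaded"
CLASSICAL = "classical"


@dataclass(frozen=True)
class CycleParameters:
    """The five rate constants of the nucleotide cycle."""

    k_on_GDP: float   # µM^-1 s^-1
    k_off_GDP: float  # s^-1
    k_on_GTP: float   # µM^-1 s^-1
    k_off_GTP: float  # s^-1
    k_cat: float      # s^-1

    def __post_init__(self) -> None:
        for name in ("k_on_GDP", "k_off_GDP", "k_on_GTP", "k_off_GTP", "k_cat"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class NucleotidePools:
    """Clamped free-nucleotide concentrations (µM), in excess over protein."""

    GTP_uM: float = DEFAULT_GTP_UM
    GDP_uM: float = DEFAULT_GDP_UM

    def __post_init__(self) -> None:
        if self.GTP_uM < 0 or self.GDP_uM < 0:
            raise InvalidInputError("pool concentrations must be nonnegative")
        if self.GTP_uM == 0 and self.GDP_uM == 0:
            raise InvalidInputError("at least one nucleotide pool must be nonzero")


@dataclass(frozen=True)
class StateDistribution:
    """Fractions of nucleotide-free, GDP-bound and GTP-bound protein."""

    f_free: float
    f_GDP: float
    f_GTP: float

    def __post_init__(self) -> None:
        vec = np.array([self.f_free, self.f_GDP, self.f_GTP])
        if np.any(vec < -1e-12) or np.any(vec > 1 + 1e-12):
            raise InvalidInputError("state fractions must lie in [0, 1]")
        if abs(vec.sum() - 1.0) > 1e-9:
            raise InvalidInputError("state fractions must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.f_free, self.f_GDP, self.f_GTP])


def steady_state_distribution(
    p: CycleParameters, pools: NucleotidePools | None = None
) -> StateDistribution:
    """Closed-form steady state of the three-state cycle.

    Degenerate limit: if GDP-bound protein cannot release its nucleotide
    (``k_off_GDP = 0``) while any flux feeds the D state, all protein ends
    up GDP-bound (``f_GDP = 1``).
    """
    pools = pools or NucleotidePools()
    gdp_influx = p.k_on_GDP * pools.GDP_uM
    gtp_influx = p.k_on_GTP * pools.GTP_uM

    denom_t = p.k_off_GTP + p.k_cat
    if gtp_influx == 0:
        t_over_f = 0.0
    elif denom_t == 0:
        t_over_f = np.inf  # T is absorbing: everything ends GTP-bound
    else:
        t_over_f = gtp_influx / denom_t
    if p.k_off_GDP == 0:
        # absorbing D state whenever anything flows into it
        if gdp_influx > 0 or (p.k_cat > 0 and gtp_influx > 0):
            return StateDistribution(0.0, 1.0, 0.0)
        d_over_f = 0.0
    else:
        if np.isinf(t_over_f):
            return StateDistribution(0.0, 0.0, 1.0)
        d_over_f = (gdp_influx + p.k_cat * t_over_f) / p.k_off_GDP
    if np.isinf(t_over_f):
        return StateDistribution(0.0, 0.0, 1.0)
    total = 1.0 + d_over_f + t_over_f
    return StateDistribution(1.0 / total, d_over_f / total, t_over_f / total)


def rate_matrix(p: CycleParameters, pools: NucleotidePools) -> np.ndarray:
    """Generator matrix M with d[F,D,T]/dt = M @ [F,D,T]."""
    a_d = p.k_on_GDP * pools.GDP_uM
    a_t = p.k_on_GTP * pools.GTP_uM
    return np.array([
        [-(a_d + a_t),  p.k_off_GDP,            p.k_off_GTP],
        [a_d,          -p.k_off_GDP,            p.k_cat],
        [a_t,           0.0,        -(p.k_off_GTP + p.k_cat)],
    ])


def integrate_cycle(
    p: CycleParameters,
    pools: NucleotidePools | None = None,
    init: StateDistribution | None = None,
    t_end: float = 1e5,
    n_eval: int = 200,
    rtol: float = 1e-10,
    atol: float = 1e-12,
):
    """Numerically integrate the cycle ODE (oracle for the closed form).

    Returns ``(times, trajectory)`` where trajectory rows are [f_free,
    f_GDP, f_GTP]. Mass is conserved by construction of the rate matrix;
    integration uses an implicit (Radau) method because the rates span
    orders of magnitude.
    """
    pools = pools or NucleotidePools()
    init = init or StateDistribution(1.0, 0.0, 0.0)
    if t_end <= 0:
        raise InvalidInputError("t_end must be positive")
    m = rate_matrix(p, pools)
    sol = solve_ivp(
        lambda _t, y: m @ y, (0.0, t_end), init.as_array(),
        method="Radau", t_eval=np.linspace(0.0, t_end, n_eval),
        rtol=rtol, atol=atol, jac=lambda _t, _y: m,
    )
    if not sol.success:
        raise RuntimeError(f"cycle ODE integration failed: {sol.message}")
    return sol.t, sol.y.T


@dataclass(frozen=True)
class ClassificationReport:
    """Exchange/hydrolysis and affinity diagnostics plus the verdict.

    ``exchange_hydrolysis_ratio`` (r1 = k_off_GDP/k_cat) compares how fast
    bound GDP leaves versus how fast bound GTP is consumed;
    ``affinity_ratio`` (r2 = K_d_GDP/K_d_GTP) > 1 means the GTP state is
    bound more tightly. The label is non-classical iff r1 exceeds its
    threshold and the steady state is majority GTP-loaded.
    """

    exchange_hydrolysis_ratio: float | None
    affinity_ratio: float | None
    steady_state: StateDistribution
    label: str
    reason: str | None = None


def classify_gtpase(
    p: CycleParameters,
    pools: NucleotidePools | None = None,
    r1_threshold: float = DEFAULT_R1_THRESHOLD,
    f_gtp_threshold: float = DEFAULT_FGTP_THRESHOLD,
) -> ClassificationReport:
    """Decide whether the parameter set describes a non-classical GTPase."""
    pools = pools or NucleotidePools()
    ss = steady_state_distribution(p, pools)
    r2 = None
    if p.k_on_GDP > 0 and p.k_on_GTP > 0 and p.k_off_GTP > 0:
        r2 = (p.k_off_GDP / p.k_on_GDP) / (p.k_off_GTP / p.k_on_GTP)
    if p.k_cat == 0:
        return ClassificationReport(
            exchange_hydrolysis_ratio=None, affinity_ratio=r2, steady_state=ss,
            label=NON_CLASSICAL, reason="undefined_ratio_no_hydrolysis",
        )
    r1 = p.k_off_GDP / p.k_cat
    label = NON_CLASSICAL if (r1 >= r1_threshold and ss.f_GTP > f_gtp_threshold) else CLASSICAL
    return ClassificationReport(
        exchange_hydrolysis_ratio=r1, affinity_ratio=r2, steady_state=ss, label=label,
    )
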