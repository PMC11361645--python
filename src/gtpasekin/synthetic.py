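"""Seeded generators for synthetic kinetics and imaging inputs.

Everything downstream (exponential fitting, the k_obs-vs-concentration
regression, hydrolysis fitting, object-based colocalization) is exercised on
the outputs of this module, so the generators carry their ground truth with
them: traces know the rate that generated them, image pairs know their true
centroid lists and colocalization fraction.

Observation models
------------------
Association (nucleotide binding under pseudo-first-order protein excess):

    F(t) = F0 + A * (1 - exp(-k_obs * t)),   k_obs = k_on*[protein] + k_off

Dissociation (chase with a large molar excess of unlabeled nucleotide, so
rebinding of the fluorescent reporter is negligible and the decay is a
single exponential):

    F(t) = F_inf + A * exp(-k_off * t)

Intrinsic GTP hydrolysis (fraction of protein-bound nucleotide still GTP):

    f_GTP(t) = exp(-k_cat * t)

Noise is additive Gaussian: for fluorescence traces its standard deviation
is a fraction of the amplitude A; for hydrolysis courses it is an absolute
sd on the fraction, which is then clipped back to [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, PlacementError, PseudoFirstOrderError

#: Default protein-concentration ladder (µM) for association experiments.
DEFAULT_LADDER_UM: tuple[float, ...] = (1.0, 2.0, 4.0, 6.0, 8.0, 10.0)

#: Default fluorescent-reporter concentration (µM).
DEFAULT_REPORTER_UM: float = 0.2

#: Minimum protein/reporter ratio for the pseudo-first-order approximation.
PSEUDO_FIRST_ORDER_EXCESS: float = 5.0

_MIN_SAMPLES = 10


@dataclass(frozen=True)
class FluorescenceTrace:
    """One stopped-flow time course: fluorescence signal versus time.

    Parameters
    ----------
    time_s
        Sample times in seconds, strictly increasing, first value >= 0.
    signal_au
        Fluorescence in arbitrary units, same length as ``time_s``.
    mode
        ``"association"`` (signal rises as reporter binds) or
        ``"dissociation"`` (signal decays as reporter is chased off).
        ``None`` for traces loaded without metadata.
    protein_conc_uM, reporter_conc_uM
        Mixing concentrations in µM; protein concentration is only
        meaningful for association traces.
    true_rate
        The generating rate constant (s^-1) when the trace is synthetic.
    """

    time_s: np.ndarray
    signal_au: np.ndarray
    mode: str | None = None
    protein_conc_uM: float | None = None
    reporter_conc_uM: float | None = None
    variant_label: str = ""
    seed: int | None = None
    true_rate: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        s = np.asarray(self.signal_au, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "signal_au", s)
        if t.ndim != 1 or s.ndim != 1 or t.size != s.size:
            raise InvalidInputError("time_s and signal_au must be 1-D and equal length")
        if t.size < _MIN_SAMPLES:
            raise InvalidInputError(f"need at least {_MIN_SAMPLES} samples, got {t.size}")
        if t[0] < 0:
            raise InvalidInputError("time_s must start at t >= 0")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("time_s must be strictly increasing")
        if self.mode not in (None, "association", "dissociation"):
            raise InvalidInputError(f"unknown trace mode {self.mode!r}")

    def __len__(self) -> int:
        return int(self.time_s.size)


@dataclass(frozen=True)
class HydrolysisTimeCourse:
    """GTP content of protein-bound nucleotide over time (HPLC readout)."""

    time_s: np.ndarray
    gtp_fraction: np.ndarray
    variant_label: str = ""
    seed: int | None = None
    true_rate: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        f = np.asarray(self.gtp_fraction, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "gtp_fraction", f)
        if t.ndim != 1 or f.ndim != 1 or t.size != f.size:
            raise InvalidInputError("time_s and gtp_fraction must be 1-D and equal length")
        if t.size < 3:
            raise InvalidInputError("need at least 3 time points")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("time_s must be strictly increasing")
        if np.any(f < 0) or np.any(f > 1):
            raise InvalidInputError("gtp_fraction values must lie in [0, 1]")

    @property
    def n_points(self) -> int:
        return int(self.time_s.size)


@dataclass(frozen=True)
class SyntheticImagePair:
    """Two-channel punctate image with known object positions.

    ``truth_centroids_a``/``_b`` are (n, 2) arrays of (row, col) pixel
    coordinates (0-based, origin top-left). The first ``n_shared`` entries
    of each list are the co-placed pairs.
    """

    channel_a: np.ndarray
    channel_b: np.ndarray
    truth_centroids_a: np.ndarray
    truth_centroids_b: np.ndarray
    true_coloc_fraction: float
    n_shared: int
    psf_sigma: float
    seed: int | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.channel_a, dtype=float)
        b = np.asarray(self.channel_b, dtype=float)
        object.__setattr__(self, "channel_a", a)
        object.__setattr__(self, "channel_b", b)
        object.__setattr__(self, "truth_centroids_a", np.asarray(self.truth_centroids_a, float))
        object.__setattr__(self, "truth_centroids_b", np.asarray(self.truth_centroids_b, float))
        if a.shape != b.shape or a.ndim != 2:
            raise InvalidInputError("channels must be 2-D grids of equal shape")
        if np.any(a < 0) or np.any(b < 0):
            raise InvalidInputError("intensities must be nonnegative")
        for cents in (self.truth_centroids_a, self.truth_centroids_b):
            if cents.size and (
                np.any(cents < 0)
                or np.any(cents[:, 0] > a.shape[0] - 1)
                or np.any(cents[:, 1] > a.shape[1] - 1)
            ):
                raise InvalidInputError("truth centroids must lie inside the grid")


def _rng(seed: int | None) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_association_trace(
    k_on: float,
    k_off: float,
    protein_conc: float,
    reporter_conc: float = DEFAULT_REPORTER_UM,
    duration: float | None = None,
    n_samples: int = 500,
    noise_sd_frac: float = 0.0,
    seed: int | None = None,
    amplitude: float = 1.0,
    offset: float = 0.1,
    variant_label: str = "",
) -> FluorescenceTrace:
    """Simulate a stopped-flow association trace.

    The generating observed rate is ``k_obs = k_on*protein_conc + k_off``;
    validity requires protein in >= 5-fold excess over the reporter so the
    binding is pseudo-first-order in the reporter. Default duration is
    ``5/k_obs`` (>= 99% of the amplitude developed).

    Raises
    ------
    PseudoFirstOrderError
        If ``protein_conc < 5 * reporter_conc``.
    InvalidInputError
        For negative rates, nonpositive duration, or zero k_obs.
    """
    if k_on < 0 or k_off < 0:
        raise InvalidInputError("rate constants must be nonnegative")
    if protein_conc <= 0 or reporter_conc <= 0:
        raise InvalidInputError("concentrations must be positive")
    if protein_conc < PSEUDO_FIRST_ORDER_EXCESS * reporter_conc:
        raise PseudoFirstOrderError(
            f"protein {protein_conc} µM must be >= {PSEUDO_FIRST_ORDER_EXCESS}x "
            f"reporter {reporter_conc} µM for pseudo-first-order kinetics"
        )
    if noise_sd_frac < 0:
        raise InvalidInputError("noise_sd_frac must be nonnegative")
    k_obs = k_on * protein_conc + k_off
    if k_obs <= 0:
        raise InvalidInputError("k_obs = k_on*[protein] + k_off must be positive")
    if duration is None:
        duration = 5.0 / k_obs
    if duration <= 0:
        raise InvalidInputError("duration must be positive")
    if n_samples < _MIN_SAMPLES:
        raise InvalidInputError(f"n_samples must be >= {_MIN_SAMPLES}")

    t = np.linspace(0.0, duration, n_samples)
    signal = offset + amplitude * (1.0 - np.exp(-k_obs * t))
    if noise_sd_frac > 0:
        signal = signal + _rng(seed).normal(0.0, noise_sd_frac * amplitude, n_samples)
    return FluorescenceTrace(
        time_s=t,
        signal_au=signal,
        mode="association",
        protein_conc_uM=float(protein_conc),
        reporter_conc_uM=float(reporter_conc),
        variant_label=variant_label,
        seed=seed,
        true_rate=float(k_obs),
    )


def simulate_dissociation_trace(
    k_off: float,
    duration: float | None = None,
    n_samples: int = 500,
    noise_sd_frac: float = 0.0,
    seed: int | None = None,
    amplitude: float = 1.0,
    offset: float = 0.1,
    variant_label: str = "",
) -> FluorescenceTrace:
    """Simulate a dissociation chase trace.

    The chase (large molar excess of unlabeled nucleotide) is modeled as
    irreversible, giving ``F(t) = F_inf + A*exp(-k_off*t)``. The decaying
    component's half-life is ``ln2/k_off``.
    """
    if k_off <= 0:
        raise InvalidInputError("k_off must be positive for a dissociation chase")
    if noise_sd_frac < 0:
        raise InvalidInputError("noise_sd_frac must be nonnegative")
    if duration is None:
        duration = 5.0 / k_off
    if duration <= 0:
        raise InvalidInputError("duration must be positive")
    if n_samples < _MIN_SAMPLES:
        raise InvalidInputError(f"n_samples must be >= {_MIN_SAMPLES}")

    t = np.linspace(0.0, duration, n_samples)
    signal = offset + amplitude * np.exp(-k_off * t)
    if noise_sd_frac > 0:
        signal = signal + _rng(seed).normal(0.0, noise_sd_frac * amplitude, n_samples)
    return FluorescenceTrace(
        time_s=t,
        signal_au=signal,
        mode="dissociation",
        reporter_conc_uM=DEFAULT_REPORTER_UM,
        variant_label=variant_label,
        seed=seed,
        true_rate=float(k_off),
    )


def simulate_association_ladder(
    k_on: float,
    k_off: float,
    ladder_uM=DEFAULT_LADDER_UM,
    reporter_conc: float = DEFAULT_REPORTER_UM,
    noise_sd_frac: float = 0.0,
    seed: int | None = None,
    **kwargs,
) -> list[FluorescenceTrace]:
    """One association trace per protein concentration of the ladder.

    Per-trace seeds are spawned deterministically from ``seed`` so the
    ladder as a whole is reproducible while traces stay independent.
    """
    ladder = [float(c) for c in ladder_uM]
    if len(ladder) < 3 or len(set(ladder)) != len(ladder):
        raise InvalidInputError("ladder needs >= 3 distinct concentrations")
    if seed is None:
        seeds: list[int | None] = [None] * len(ladder)
    else:
        ss = np.random.SeedSequence(seed)
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(ladder))]
    return [
        simulate_association_trace(
            k_on, k_off, conc, reporter_conc,
            noise_sd_frac=noise_sd_frac, seed=s, **kwargs,
        )
        for conc, s in zip(ladder, seeds)
    ]


def simulate_hydrolysis_timecourse(
    k_cat: float,
    t_max: float | None = None,
    n_points: int = 6,
    noise_sd: float = 0.0,
    seed: int | None = None,
    variant_label: str = "",
) -> HydrolysisTimeCourse:
    """Simulate an HPLC GTP-content time course.

    Intrinsic hydrolysis of bound GTP is first order,
    ``f_GTP(t) = exp(-k_cat*t)``; six sampling points spanning three
    half-lives by default. Noisy fractions are clipped to [0, 1].
    """
    if k_cat < 0:
        raise InvalidInputError("k_cat must be nonnegative")
    if n_points < 3:
        raise InvalidInputError("n_points must be >= 3")
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be nonnegative")
    if t_max is None:
        if k_cat == 0:
            raise InvalidInputError("t_max is required when k_cat is 0")
        t_max = 3.0 * math.log(2.0) / k_cat
    if t_max <= 0:
        raise InvalidInputError("t_max must be positive")

    t = np.linspace(0.0, t_max, n_points)
    frac = np.exp(-k_cat * t)
    if noise_sd > 0:
        frac = np.clip(frac + _rng(seed).normal(0.0, noise_sd, n_points), 0.0, 1.0)
    return HydrolysisTimeCourse(
        time_s=t, gtp_fraction=frac,
        variant_label=variant_label, seed=seed, true_rate=float(k_cat),
    )


def _render_spots(shape, centroids, psf_sigma, rng, background_sd):
    img = np.zeros(shape, dtype=float)
    rows = np.arange(shape[0], dtype=float)
    cols = np.arange(shape[1], dtype=float)
    half = max(1, int(math.ceil(4 * psf_sigma)))
    for r0, c0 in centroids:
        r_lo, r_hi = max(0, int(r0) - half), min(shape[0], int(r0) + half + 1)
        c_lo, c_hi = max(0, int(c0) - half), min(shape[1], int(c0) + half + 1)
        dr = rows[r_lo:r_hi, None] - r0
        dc = cols[None, c_lo:c_hi] - c0
        img[r_lo:r_hi, c_lo:c_hi] += np.exp(-(dr**2 + dc**2) / (2 * psf_sigma**2))
    if background_sd > 0:
        img = img + rng.normal(0.0, background_sd, shape)
    return np.clip(img, 0.0, None)


def generate_image_pair(
    n_objects: int,
    coloc_fraction: float,
    grid_shape: tuple[int, int] = (256, 256),
    psf_sigma: float = 2.0,
    min_separation: float = 10.0,
    background_sd: float = 0.0,
    jitter: float = 0.0,
    seed: int | None = None,
    max_tries: int = 10_000,
) -> SyntheticImagePair:
    """Generate a two-channel punctate image pair with known colocalization.

    ``round(coloc_fraction*n_objects)`` spot centers are shared between
    channels (displaced by at most ``jitter`` px); every other center is at
    least ``min_separation`` px from all centers of the other channel, so a
    downstream centroid matcher with tolerance < min_separation recovers the
    true fraction exactly on clean images. Spots are isotropic Gaussians of
    width ``psf_sigma`` on optional Gaussian background noise.
    """
    if n_objects < 1:
        raise InvalidInputError("n_objects must be >= 1")
    if not 0.0 <= coloc_fraction <= 1.0:
        raise InvalidInputError("coloc_fraction must lie in [0, 1]")
    if min_separation <= 0 or psf_sigma <= 0:
        raise InvalidInputError("min_separation and psf_sigma must be positive")
    if jitter < 0 or jitter > 0.5:
        raise InvalidInputError("jitter must lie in [0, 0.5] px")
    rng = _rng(seed)
    n_shared = int(round(coloc_fraction * n_objects))
    margin = 4 * psf_sigma + 1
    lo = (margin, margin)
    hi = (grid_shape[0] - margin, grid_shape[1] - margin)
    if hi[0] <= lo[0] or hi[1] <= lo[1]:
        raise InvalidInputError("grid too small for psf margin")

    def draw() -> np.ndarray:
        return np.array([rng.uniform(lo[0], hi[0]), rng.uniform(lo[1], hi[1])])

    def far_enough(p, others, d) -> bool:
        return all(np.hypot(*(p - q)) >= d for q in others)

    cents_a: list[np.ndarray] = []
    tries = 0
    while len(cents_a) < n_objects:
        if tries > max_tries:
            raise PlacementError("could not place channel-A objects; lower n_objects or min_separation")
        tries += 1
        p = draw()
        if far_enough(p, cents_a, min_separation):
            cents_a.append(p)

    cents_b: list[np.ndarray] = []
    for k in range(n_shared):
        p = cents_a[k].copy()
        if jitter > 0:
            ang = rng.uniform(0, 2 * math.pi)
            rad = rng.uniform(0, jitter)
            p = p + rad * np.array([math.cos(ang), math.sin(ang)])
        cents_b.append(p)
    tries = 0
    while len(cents_b) < n_objects:
        if tries > max_tries:
            raise PlacementError("could not place channel-B objects; lower n_objects or min_separation")
        tries += 1
        p = draw()
        # non-shared B spots keep clear of every A spot and of other B spots
        if far_enough(p, cents_a, min_separation) and far_enough(p, cents_b, min_separation):
            cents_b.append(p)

    arr_a = np.array(cents_a)
    arr_b = np.array(cents_b)
    img_a = _render_spots(grid_shape, arr_a, psf_sigma, rng, background_sd)
    img_b = _render_spots(grid_shape, arr_b, psf_sigma, rng, background_sd)
    return SyntheticImagePair(
        channel_a=img_a, channel_b=img_b,
        truth_centroids_a=arr_a, truth_centroids_b=arr_b,
        true_coloc_fraction=float(coloc_fraction),
        n_shared=n_shared, psf_sigma=float(psf_sigma), seed=seed,
    )
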