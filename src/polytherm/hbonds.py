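"""Hydrogen-bond detection, density, autocorrelation and lifetimes.

A hydrogen bond is a geometric event: donor-acceptor distance below
0.35 nm and hydrogen-donor-acceptor angle (measured at the donor) below
30 degrees, both under the minimum-image convention. The bond-existence
traces h_i(t) feed an intermittent time autocorrelation

    C_HB(tau) = < sum_i h_i(t) h_i(t+tau) >_t / < sum_i h_i(t) >_t,

normalized so C_HB(0) = 1; re-formed bonds count, which is what makes
the very long lifetimes of glassy polymer systems observable at all.
C_HB is fitted with a constrained sum of exponentials
sum_i K_i exp(-tau/tau_i) (K_i >= 0, sum K_i = 1) and the average
lifetime is the trapezoidal integral of the observed curve plus the
analytic integral of the fitted tail out to a horizon (default 100 ns).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from polytherm.core.geometry import min_image_displacement
from polytherm.core.types import PolythermError, TimeSeries, Trajectory

D_MAX_DEFAULT = 0.35  # nm, donor-acceptor
ANGLE_MAX_DEFAULT = 30.0  # degrees, hydrogen-donor-acceptor at the donor
COVALENT_DH_MAX = 0.12  # nm, hydrogen-to-donor attachment cutoff
DEFAULT_HORIZON_PS = 1.0e5  # 100 ns


@dataclass
class BondOccupancy:
    """Binary bond-existence matrix h_i(t): rows are bonds, columns frames."""

    matrix: np.ndarray  # (n_bonds, n_frames) of {0, 1}
    triples: List[Tuple[int, int, int]]  # (donor, hydrogen, acceptor) atom indices
    times: np.ndarray  # ps
    pair_tags: Optional[np.ndarray] = None  # 'PP' | 'PW' | 'WW' per bond

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        self.times = np.asarray(self.times, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("occupancy must be a 2-D (bond, frame) matrix")
        if self.matrix.shape[0] != len(self.triples):
            raise ValueError("one triple required per bond row")
        if self.matrix.shape[1] != len(self.times):
            raise ValueError("one time stamp required per frame column")
        if len(set(self.triples)) != len(self.triples):
            raise ValueError("bond triples must be unique")
        if np.any(self.matrix > 1):
            raise ValueError("occupancy entries must be 0 or 1")
        if self.pair_tags is not None and len(self.pair_tags) != len(self.triples):
            raise ValueError("one pair tag required per bond")

    @property
    def n_bonds(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[1]

    def select(self, tag: str) -> "BondOccupancy":
        """Sub-population with a given species-pair tag (PP, PW or WW)."""
        if self.pair_tags is None:
            raise ValueError("occupancy carries no pair tags")
        mask = self.pair_tags == tag
        idx = np.flatnonzero(mask)
        return BondOccupancy(
            matrix=self.matrix[mask],
            triples=[self.triples[i] for i in idx],
            times=self.times,
            pair_tags=self.pair_tags[mask],
        )


@dataclass
class Autocorrelation:
    """C_HB on a lag grid, normalized to C(0) = 1."""

    lags: np.ndarray  # ps
    values: np.ndarray

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags.shape != self.values.shape:
            raise ValueError("lags and values must match")
        if len(self.values) and abs(self.values[0] - 1.0) > 1e-9:
            raise ValueError("autocorrelation must be normalized to C(0) = 1")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"lag (ps)": self.lags, "C_HB": self.values})


@dataclass
class DecayFit:
    """Constrained multi-exponential fit of C_HB."""

    weights: np.ndarray  # K_i, sum to 1
    taus: np.ndarray  # ps
    residual: float
    flags: Tuple[str, ...] = ()

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.sum(self.weights[:, None] * np.exp(-t[None, :] / self.taus[:, None]), axis=0)

    @property
    def dominant_tau(self) -> float:
        """Time constant of the heaviest-weighted decay process."""
        return float(self.taus[int(np.argmax(self.weights))])


@dataclass
class LifetimeResult:
    lifetime_ps: float
    horizon_ps: float
    observed_integral_ps: float
    tail_integral_ps: float
    lower_bound: bool  # True when C had not decayed below 0.5 inside the window


def _attach_hydrogens(traj: Trajectory) -> List[Tuple[int, int]]:
    """Pair each hydrogen with its covalently bonded donor (nearest donor
    within COVALENT_DH_MAX in the first frame)."""
    atoms = traj.atoms
    donors = np.flatnonzero(atoms.is_donor)
    hydrogens = np.flatnonzero(atoms.is_hydrogen)
    if len(donors) == 0 or len(hydrogens) == 0:
        return []
    box = traj.boxes[0]
    pos = traj.coordinates[0]
    pairs = []
    for h in hydrogens:
        d = min_image_displacement(pos[donors] - pos[h], box)
        r = np.sqrt(np.sum(d * d, axis=1))
        j = int(np.argmin(r))
        if r[j] <= COVALENT_DH_MAX:
            pairs.append((int(donors[j]), int(h)))
    return pairs


def _pair_tag(species_d: str, species_a: str) -> str:
    water = {"water", "W", "w"}
    d_w, a_w = species_d in water, species_a in water
    if d_w and a_w:
        return "WW"
    if d_w or a_w:
        return "PW"
    return "PP"


def detect_hbonds(
    traj: Trajectory,
    d_max: float = D_MAX_DEFAULT,
    angle_max: float = ANGLE_MAX_DEFAULT,
) -> BondOccupancy:
    """Geometric hydrogen-bond detection over all frames.

    Requires donor/acceptor/hydrogen role flags on the trajectory's
    atoms. Hydrogens are attached to their nearest donor within
    0.12 nm (first frame); a (donor, hydrogen, acceptor) triple is
    bonded in a frame iff the donor-acceptor distance is below ``d_max``
    and the H-D-A angle at the donor is below ``angle_max`` degrees.
    """
    atoms = traj.atoms
    if atoms.is_donor is None or atoms.is_acceptor is None or atoms.is_hydrogen is None:
        raise PolythermError("donor/acceptor/hydrogen role flags are required for H-bond detection")
    dh_pairs = _attach_hydrogens(traj)
    acceptors = np.flatnonzero(atoms.is_acceptor)
    cos_max = np.cos(np.deg2rad(angle_max))
    presence: dict[Tuple[int, int, int], np.ndarray] = {}
    n_frames = traj.n_frames
    for f in range(n_frames):
        pos = traj.coordinates[f]
        box = traj.boxes[f]
        for d_idx, h_idx in dh_pairs:
            if len(acceptors) == 0:
                continue
            acc = acceptors[acceptors != d_idx]
            if len(acc) == 0:
                continue
            da = min_image_displacement(pos[acc] - pos[d_idx], box)
            r_da = np.sqrt(np.sum(da * da, axis=1))
            within = r_da < d_max
            if not within.any():
                continue
            dh = min_image_displacement(pos[h_idx] - pos[d_idx], box)
            r_dh = np.sqrt(np.sum(dh * dh))
            cosang = (da[within] @ dh) / (r_da[within] * r_dh)
            ok = cosang > cos_max
            for a_idx in acc[within][ok]:
                key = (d_idx, h_idx, int(a_idx))
                if key not in presence:
                    presence[key] = np.zeros(n_frames, dtype=np.uint8)
                presence[key][f] = 1
    triples = sorted(presence)
    matrix = (
        np.stack([presence[t] for t in triples])
        if triples
        else np.zeros((0, n_frames), dtype=np.uint8)
    )
    if atoms.species is not None:
        tags = np.array(
            [_pair_tag(str(atoms.species[d]), str(atoms.species[a])) for d, _, a in triples],
            dtype=object,
        )
    else:
        tags = None
    return BondOccupancy(matrix=matrix, triples=list(triples), times=traj.times, pair_tags=tags)


def hbond_density(occ: BondOccupancy, box_volumes_nm3: Sequence[float]) -> float:
    """Average bonds per nm^3: mean over frames of (bonds in frame)/V(frame)."""
    volumes = np.asarray(
        box_volumes_nm3.values if isinstance(box_volumes_nm3, TimeSeries) else box_volumes_nm3,
        dtype=float,
    )
    if len(volumes) != occ.n_frames:
        raise PolythermError(
            f"volume series has {len(volumes)} entries but occupancy has {occ.n_frames} frames"
        )
    if occ.n_bonds == 0:
        return 0.0
    counts = occ.matrix.sum(axis=0)
    return float(np.mean(counts / volumes))


def hbond_autocorrelation(occ: BondOccupancy, max_lag_ps: Optional[float] = None) -> Autocorrelation:
    """Intermittent autocorrelation of the bond-existence traces.

    C(tau) = <sum_i h_i(t) h_i(t+tau)>_t / <sum_i h_i(t)>_t with the
    time averages taken over all valid origins, then normalized so that
    C(0) = 1. Computed with FFTs over the time axis.
    """
    if occ.n_frames < 2:
        raise ValueError("need at least 2 frames for an autocorrelation")
    h = occ.matrix.astype(float)
    if occ.n_bonds == 0 or h.sum() == 0:
        raise PolythermError("no bonds present: autocorrelation undefined")
    t_len = occ.n_frames
    n_fft = 1 << int(np.ceil(np.log2(2 * t_len)))
    spectrum = np.fft.rfft(h, n=n_fft, axis=1)
    corr = np.fft.irfft(spectrum * np.conj(spectrum), n=n_fft, axis=1)[:, :t_len]
    raw = corr.sum(axis=0)  # sum_i sum_t h_i(t) h_i(t+tau)
    origins = t_len - np.arange(t_len)
    c = raw / origins  # per-origin average
    c /= c[0]
    dt = float(np.mean(np.diff(occ.times)))
    lags = np.arange(t_len) * dt
    if max_lag_ps is not None:
        keep = lags <= max_lag_ps
        lags, c = lags[keep], c[keep]
    return Autocorrelation(lags=lags, values=c)


def _fit_once(t: np.ndarray, c: np.ndarray, tau0: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    n = len(tau0)
    if n == 1:
        def resid(theta):
            return np.exp(-t / np.exp(theta[0])) - c

        sol = least_squares(resid, x0=[np.log(tau0[0])], method="lm", max_nfev=2000)
        return np.array([1.0]), np.array([np.exp(sol.x[0])]), float(np.sum(sol.fun**2))

    # weights via squared-softmax-style parameterization keeps K_i >= 0, sum K_i = 1
    def unpack(theta):
        w = theta[:n] ** 2
        k = w / w.sum()
        taus = np.exp(theta[n:])
        return k, taus

    def resid(theta):
        k, taus = unpack(theta)
        model = np.sum(k[:, None] * np.exp(-t[None, :] / taus[:, None]), axis=0)
        return model - c

    theta0 = np.concatenate([np.ones(n), np.log(tau0)])
    sol = least_squares(resid, x0=theta0, method="trf", max_nfev=5000)
    k, taus = unpack(sol.x)
    return k, taus, float(np.sum(sol.fun**2))


def fit_decay(
    corr: Autocorrelation,
    n_terms: int = 2,
    n_starts: int = 8,
    max_fit_points: int = 200,
) -> DecayFit:
    """Constrained multi-exponential fit of C_HB(tau).

    Fits sum_i K_i exp(-tau/tau_i) with K_i >= 0, sum K_i = 1, tau_i > 0
    by multi-start nonlinear least squares (time-constant guesses
    log-spaced over the lag range). The fit grid is log-spaced so the
    residuals balance short and long times.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    t, c = corr.lags, corr.values
    if len(t) < n_terms + 2:
        raise ValueError("too few lag points for the requested number of terms")
    # log-spaced subsample of the lag grid (always keep tau = 0)
    if len(t) > max_fit_points:
        idx = np.unique(
            np.concatenate(
                [[0], np.geomspace(1, len(t) - 1, max_fit_points - 1).astype(int)]
            )
        )
        t_fit, c_fit = t[idx], c[idx]
    else:
        t_fit, c_fit = t, c
    t_max = t[-1]
    dt = t[1] - t[0] if len(t) > 1 else 1.0
    guesses = np.geomspace(max(dt, 1e-6), 10.0 * t_max, n_starts)
    best: Optional[tuple] = None
    for g in guesses:
        tau0 = g * np.geomspace(1.0, 20.0, n_terms)
        try:
            k, taus, res = _fit_once(t_fit, c_fit, tau0)
        except Exception:
            continue
        if best is None or res < best[2]:
            best = (k, taus, res)
    if best is None:
        raise PolythermError(
            f"decay fit failed to converge from {n_starts} starts "
            f"(n_terms={n_terms}, {len(t_fit)} fit points, lag range 0-{t_max} ps)"
        )
    k, taus, res = best
    flags = []
    tau_cap = 100.0 * t_max
    if np.any(taus > tau_cap):
        taus = np.minimum(taus, tau_cap)
        flags.append("time constant at upper bound: decay not resolved within the window")
    order = np.argsort(taus)
    return DecayFit(weights=k[order], taus=taus[order], residual=res, flags=tuple(flags))


def hbond_lifetime(
    corr: Autocorrelation,
    fit: Optional[DecayFit] = None,
    horizon_ps: float = DEFAULT_HORIZON_PS,
) -> LifetimeResult:
    """Average lifetime: trapezoidal integral of C plus the fitted tail.

    Integrates the observed C over [0, t_max] with the trapezoid rule;
    beyond t_max the fitted decay is integrated analytically up to the
    horizon: sum_i K_i tau_i (exp(-t_max/tau_i) - exp(-horizon/tau_i)).
    Flagged as a lower bound when C(t_max) > 0.5 — the population had
    not half-decayed inside the observation window.
    """
    t, c = corr.lags, corr.values
    t_max = float(t[-1])
    if horizon_ps < t_max:
        raise ValueError(f"horizon {horizon_ps} ps is shorter than the observed window {t_max} ps")
    observed = float(np.trapezoid(c, t))
    tail = 0.0
    if horizon_ps > t_max:
        if fit is None:
            raise PolythermError("a decay fit is required to extrapolate beyond the observed window")
        tail = float(
            np.sum(fit.weights * fit.taus * (np.exp(-t_max / fit.taus) - np.exp(-horizon_ps / fit.taus)))
        )
    return LifetimeResult(
        lifetime_ps=observed + tail,
        horizon_ps=float(horizon_ps),
        observed_integral_ps=observed,
        tail_integral_ps=tail,
        lower_bound=bool(c[-1] > 0.5),
    )
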