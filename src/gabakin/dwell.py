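"""Single-channel dwell-time theory, stochastic simulation and fitting.

Under Markov gating, the durations of sojourns in the open (or shut) class
are distributed as a mixture of exponentials whose time constants are the
reciprocal eigenvalues of the negated class submatrix of the generator.
This module computes those theoretical mixtures, draws exact stochastic
trajectories (Gillespie), imposes a recording dead time, fits exponential
mixtures to dwell lists by maximum likelihood (EM, with left truncation at
the dead time), and groups openings into bursts with a critical shut time.

Durations are handled in milliseconds throughout, matching how patch-clamp
dwell lists are reported; rates inside schemes stay in s^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

from .schemes import KineticScheme, q_matrix, steady_state

__all__ = [
    "ExpMixture",
    "DwellSequence",
    "BurstSet",
    "theoretical_dwell_mixture",
    "mean_open_time",
    "gillespie_simulate",
    "ensemble_popen",
    "impose_dead_time",
    "fit_exp_mixture",
    "burst_analysis",
    "critical_shut_time",
]


@dataclass(frozen=True)
class ExpMixture:
    """Exponential mixture: time constants (ms) and area fractions."""

    taus_ms: tuple[float, ...]
    fractions: tuple[float, ...]
    loglik: float | None = None
    converged: bool = True
    n: int | None = None
    dead_time_ms: float = 0.0

    def __post_init__(self):
        taus = np.asarray(self.taus_ms)
        fracs = np.asarray(self.fractions)
        if taus.size != fracs.size:
            raise ValueError("taus and fractions differ in length")
        if (taus <= 0).any():
            raise ValueError("time constants must be positive")
        if abs(fracs.sum() - 1.0) > 1e-6 or (fracs < -1e-12).any():
            raise ValueError("fractions must be non-negative and sum to 1")
        if not np.all(np.diff(taus) >= 0):
            raise ValueError("time constants must be sorted ascending")

    @property
    def n_components(self) -> int:
        return len(self.taus_ms)

    def mean_ms(self) -> float:
        return float(np.dot(self.taus_ms, self.fractions))

    def pdf(self, t_ms):
        t = np.asarray(t_ms, dtype=float)
        taus = np.asarray(self.taus_ms)
        fr = np.asarray(self.fractions)
        return np.sum(fr / taus * np.exp(-t[..., None] / taus), axis=-1)

    def cdf(self, t_ms):
        t = np.asarray(t_ms, dtype=float)
        taus = np.asarray(self.taus_ms)
        fr = np.asarray(self.fractions)
        return np.sum(fr * (1.0 - np.exp(-t[..., None] / taus)), axis=-1)

    def to_dict(self) -> dict:
        return {
            "taus_ms": list(self.taus_ms),
            "fractions": list(self.fractions),
            "loglik": self.loglik,
            "n": self.n,
            "dead_time_ms": self.dead_time_ms,
            "converged": self.converged,
        }


@dataclass
class DwellSequence:
    """Alternating (after merging) open/shut sojourn durations.

    ``states`` holds the index of the underlying scheme state for each
    sojourn (-1 once censoring has merged states of a class), ``open`` the
    conductance class, ``durations_ms`` the sojourn lengths.
    """

    durations_ms: np.ndarray
    open: np.ndarray
    states: np.ndarray
    scheme_name: str = ""
    seed: int | None = None
    dead_time_ms: float = 0.0

    def __post_init__(self):
        if not (len(self.durations_ms) == len(self.open) == len(self.states)):
            raise ValueError("dwell arrays differ in length")
        if (np.asarray(self.durations_ms) <= 0).any():
            raise ValueError("dwell durations must be positive")

    def __len__(self) -> int:
        return len(self.durations_ms)

    def alternating(self) -> "DwellSequence":
        """Merge consecutive same-class sojourns into class dwells."""
        if len(self) == 0:
            return self
        open_arr = np.asarray(self.open, dtype=bool)
        change = np.flatnonzero(np.diff(open_arr.astype(int))) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(self)]])
        durations = np.add.reduceat(self.durations_ms, starts)
        # representative state: the longest constituent sojourn
        states = np.empty(len(starts), dtype=int)
        for k, (a, b) in enumerate(zip(starts, ends)):
            states[k] = self.states[a + int(np.argmax(self.durations_ms[a:b]))]
        return DwellSequence(durations, open_arr[starts].copy(), states,
                            self.scheme_name, self.seed, self.dead_time_ms)

    def class_durations(self, open_class: bool) -> np.ndarray:
        alt = self.alternating()
        return alt.durations_ms[alt.open == open_class]


@dataclass(frozen=True)
class BurstSet:
    """Openings grouped by a critical shut time."""

    t_crit_ms: float
    n_openings: np.ndarray
    durations_ms: np.ndarray

    def __post_init__(self):
        if self.t_crit_ms <= 0:
            raise ValueError("t_crit must be positive")
        if (np.asarray(self.n_openings) < 1).any():
            raise ValueError("every burst has at least one opening")

    @property
    def mean_openings_per_burst(self) -> float:
        return float(np.mean(self.n_openings))


# ---------------------------------------------------------------------------
# theory


def theoretical_dwell_mixture(scheme: KineticScheme,
                              concentrations: Mapping[str, float] | None = None,
                              klass: str = "open",
                              p: np.ndarray | None = None) -> ExpMixture:
    """Exponential mixture of sojourn times in the open or shut class.

    The class sub-generator ``Q_AA`` governs the sojourn: the density is
    ``phi exp(Q_AA t) (-Q_AA) 1`` with entry vector ``phi`` proportional to
    the steady-state probability flux from the complementary class.  Time
    constants are the negative reciprocal eigenvalues of ``Q_AA``;
    fractions are the areas of the corresponding components.
    """
    if klass not in ("open", "shut"):
        raise ValueError("klass must be 'open' or 'shut'")
    mask = scheme.class_mask(klass)
    if not mask.any():
        raise ValueError(f"scheme {scheme.name!r} has no {klass} states")
    Q = q_matrix(scheme, concentrations or {})
    if p is None:
        p = steady_state(Q, scheme.state_names)
    A = np.flatnonzero(mask)
    F = np.flatnonzero(~mask)
    Q_AA = Q[np.ix_(A, A)]
    Q_FA = Q[np.ix_(F, A)]
    phi = p[F] @ Q_FA
    total = phi.sum()
    if total <= 0:
        raise ValueError(
            f"no steady-state flux into the {klass} class; the class is "
            "unreachable at these concentrations"
        )
    phi = phi / total
    lam, V = np.linalg.eig(Q_AA)
    if np.abs(lam.imag).max(initial=0.0) > 1e-9 * np.abs(lam.real).max():
        raise np.linalg.LinAlgError("complex dwell eigenvalues; scheme is far from reversible")
    lam = lam.real
    V = V.real
    u = -Q_AA @ np.ones(len(A))
    c = (phi @ V) * np.linalg.solve(V, u)
    taus_s = -1.0 / lam
    fractions = c * taus_s
    fractions = np.where(np.abs(fractions) < 1e-12, 0.0, fractions)
    keep = fractions > 0
    taus_s, fractions = taus_s[keep], fractions[keep]
    fractions = fractions / fractions.sum()
    order = np.argsort(taus_s)
    return ExpMixture(tuple(taus_s[order] * 1e3), tuple(fractions[order]))


def mean_open_time(scheme: KineticScheme,
                   concentrations: Mapping[str, float] | None = None) -> float:
    """Mean open time (ms): area-weighted mean of the open mixture."""
    return theoretical_dwell_mixture(scheme, concentrations, "open").mean_ms()


# ---------------------------------------------------------------------------
# stochastic simulation


def _jump_tables(Q: np.ndarray):
    rates = -np.diag(Q)
    n = Q.shape[0]
    cum = []
    targets = []
    for i in range(n):
        row = Q[i].copy()
        row[i] = 0.0
        nz = np.flatnonzero(row > 0)
        if nz.size:
            c = np.cumsum(row[nz])
            cum.append(c / c[-1])
        else:
            cum.append(np.array([]))
        targets.append(nz)
    return rates, cum, targets


def gillespie_simulate(scheme: KineticScheme,
                       concentrations: Mapping[str, float] | None = None,
                       n_events: int | None = None,
                       duration_s: float | None = None,
                       n_openings: int | None = None,
                       seed: int | None = None,
                       start_state: str | None = None) -> DwellSequence:
    """Exact continuous-time Markov-chain trajectory of a single channel.

    Stops after ``n_events`` sojourns, ``duration_s`` of simulated time, or
    ``n_openings`` completed open sojourns, whichever is given (at least
    one is required).  The starting state is drawn from the stationary
    distribution unless ``start_state`` names one.  Reproducible by seed.
    """
    if n_events is None and duration_s is None and n_openings is None:
        raise ValueError("give n_events, duration_s or n_openings")
    rng = np.random.default_rng(seed)
    Q = q_matrix(scheme, concentrations or {})
    rates, cum, targets = _jump_tables(Q)
    open_mask = scheme.open_mask
    if start_state is None:
        p = steady_state(Q, scheme.state_names)
        state = int(rng.choice(len(p), p=p))
    else:
        state = scheme.state_index(start_state)

    states: list[int] = []
    durations: list[float] = []
    opens: list[bool] = []
    t = 0.0
    n_open_done = 0
    while True:
        if n_events is not None and len(states) >= n_events:
            break
        if duration_s is not None and t >= duration_s:
            break
        if n_openings is not None and n_open_done >= n_openings:
            break
        rate = rates[state]
        if rate <= 0:
            # absorbing at these concentrations: fill out the requested
            # duration if one was given, then stop
            if duration_s is not None and t < duration_s:
                states.append(state)
                durations.append((duration_s - t) * 1e3)
                opens.append(bool(open_mask[state]))
            break
        dwell = rng.exponential(1.0 / rate)
        states.append(state)
        durations.append(dwell * 1e3)
        opens.append(bool(open_mask[state]))
        if open_mask[state]:
            n_open_done += 1
        t += dwell
        u = rng.random()
        k = int(np.searchsorted(cum[state], u))
        state = int(targets[state][k])
    return DwellSequence(
        durations_ms=np.asarray(durations),
        open=np.asarray(opens, dtype=bool),
        states=np.asarray(states, dtype=int),
        scheme_name=scheme.name,
        seed=seed,
    )


def ensemble_popen(scheme: KineticScheme, protocol, t_grid: np.ndarray,
                   n_traj: int = 10_000, seed: int | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo open probability: mean over ``n_traj`` exact trajectories.

    Independent stochastic oracle for the matrix-exponential propagation
    (exchange smoothing is not modelled here).  Returns ``(popen, se)`` on
    ``t_grid``; ``se`` is the binomial standard error of the mean.
    """
    from .simulate import _fill_concentrations  # local import avoids cycle

    rng = np.random.default_rng(seed)
    t_grid = np.asarray(t_grid, dtype=float)
    open_mask = scheme.open_mask
    seg_concs = [_fill_concentrations(c, protocol.ligands) for _, c in protocol.segments]
    Q0 = q_matrix(scheme, seg_concs[0])
    p0 = steady_state(Q0, scheme.state_names)
    states = rng.choice(len(p0), size=n_traj, p=p0)

    counts = np.zeros(t_grid.size + 1)
    t_now = np.zeros(n_traj)
    seg_start = 0.0
    for (duration, _), conc in zip(protocol.segments, seg_concs):
        seg_end = seg_start + duration
        Q = q_matrix(scheme, conc)
        rates = -np.diag(Q)
        jump_p = np.where(rates[:, None] > 0, Q / np.where(rates[:, None] > 0, rates[:, None], 1.0), 0.0)
        np.fill_diagonal(jump_p, 0.0)
        cum_p = np.cumsum(jump_p, axis=1)
        # normalize guard for absorbing states
        last = cum_p[:, -1]
        cum_p[last > 0] /= last[last > 0, None]

        active = np.arange(n_traj)
        while active.size:
            s = states[active]
            r = rates[s]
            dwell = np.full(active.size, np.inf)
            pos = r > 0
            dwell[pos] = rng.exponential(1.0 / r[pos])
            t_end = np.minimum(t_now[active] + dwell, seg_end)
            # accumulate open occupancy over [t_now, t_end)
            is_open = open_mask[s]
            if is_open.any():
                i0 = np.searchsorted(t_grid, t_now[active][is_open], side="left")
                i1 = np.searchsorted(t_grid, t_end[is_open], side="left")
                np.add.at(counts, i0, 1.0)
                np.add.at(counts, i1, -1.0)
            jumped = (t_now[active] + dwell) < seg_end
            idx_j = active[jumped]
            if idx_j.size:
                u = rng.random(idx_j.size)
                rows = cum_p[states[idx_j]]
                states[idx_j] = (u[:, None] > rows).sum(axis=1)
            t_now[active] = t_end
            active = active[jumped]
        t_now[:] = seg_end
        seg_start = seg_end
    occ = np.cumsum(counts)[:-1] / n_traj
    se = np.sqrt(np.clip(occ * (1 - occ), 0, None) / n_traj)
    return occ, se


# ---------------------------------------------------------------------------
# censoring, fitting, bursts


def impose_dead_time(dwells: DwellSequence, dead_time_ms: float) -> DwellSequence:
    """Merge events shorter than the dead time into the enclosing dwell.

    Mimics the finite time resolution of an idealized recording: an
    unresolved gap (or opening) is concatenated, together with the
    following same-class dwell, onto the preceding resolved dwell of the
    opposite class.  Leading unresolved events are dropped.  Idempotent at
    fixed dead time.
    """
    if dead_time_ms < 0:
        raise ValueError("dead time must be >= 0")
    alt = dwells.alternating()
    if dead_time_ms == 0 or len(alt) == 0:
        return alt
    dur = alt.durations_ms
    opn = alt.open
    stt = alt.states
    first = 0
    while first < len(dur) and dur[first] < dead_time_ms:
        first += 1
    if first == len(dur):
        return DwellSequence(np.array([]), np.array([], dtype=bool),
                             np.array([], dtype=int), dwells.scheme_name,
                             dwells.seed, dead_time_ms)
    out_dur = [float(dur[first])]
    out_open = [bool(opn[first])]
    out_state = [int(stt[first])]
    for i in range(first + 1, len(dur)):
        if opn[i] == out_open[-1]:
            out_dur[-1] += float(dur[i])
        elif dur[i] < dead_time_ms:
            out_dur[-1] += float(dur[i])  # unresolved opposite-class gap
        else:
            out_dur.append(float(dur[i]))
            out_open.append(bool(opn[i]))
            out_state.append(int(stt[i]))
    return DwellSequence(np.asarray(out_dur), np.asarray(out_open, dtype=bool),
                         np.asarray(out_state, dtype=int), dwells.scheme_name,
                         dwells.seed, dead_time_ms)


def fit_exp_mixture(durations_ms, n_components: int,
                    dead_time_ms: float = 0.0, n_starts: int = 10,
                    seed: int = 0, max_iter: int = 2000,
                    tol: float = 1e-10) -> ExpMixture:
    """Maximum-likelihood exponential mixture for dwell durations.

    Durations are left-truncated at the dead time; because the exponential
    is memoryless the truncated likelihood reduces to an ordinary mixture
    on the excess durations ``t - dead_time``, maximized here by EM from
    ``n_starts`` deterministic multi-starts.  Time constants are reported
    on the original scale (they are unchanged by the truncation).
    """
    x = np.asarray(durations_ms, dtype=float)
    if (x <= dead_time_ms).any():
        raise ValueError("all durations must exceed the dead time")
    if x.size < 10 * n_components:
        raise ValueError(
            f"need at least {10 * n_components} durations to fit "
            f"{n_components} components, got {x.size}"
        )
    x = x - dead_time_ms
    x = np.clip(x, 1e-12, None)
    if n_components == 1:
        tau = float(np.mean(x))
        ll = float(-x.size * np.log(tau) - x.sum() / tau)
        return ExpMixture((tau,), (1.0,), loglik=ll, n=x.size,
                          dead_time_ms=dead_time_ms)

    rng = np.random.default_rng(seed)
    qs = np.quantile(x, (np.arange(n_components) + 1) / (n_components + 1))
    qs = np.clip(qs, 1e-9, None)
    best = None
    for _ in range(n_starts):
        taus = qs * np.exp(rng.normal(0.0, 0.7, n_components))
        fracs = np.full(n_components, 1.0 / n_components)
        ll_prev = -np.inf
        converged = False
        for _ in range(max_iter):
            dens = fracs / taus * np.exp(-x[:, None] / taus)
            tot = dens.sum(axis=1)
            tot = np.clip(tot, 1e-300, None)
            ll = float(np.log(tot).sum())
            resp = dens / tot[:, None]
            w = resp.sum(axis=0)
            w = np.clip(w, 1e-12, None)
            taus = (resp * x[:, None]).sum(axis=0) / w
            taus = np.clip(taus, 1e-9, None)
            fracs = w / x.size
            if ll - ll_prev < tol * max(1.0, abs(ll)):
                converged = True
                ll_prev = ll
                break
            ll_prev = ll
        if best is None or ll_prev > best[0]:
            best = (ll_prev, taus.copy(), fracs.copy(), converged)
    ll, taus, fracs, converged = best
    order = np.argsort(taus)
    fracs = fracs[order] / fracs.sum()
    return ExpMixture(tuple(taus[order]), tuple(fracs), loglik=float(ll),
                      converged=bool(converged), n=x.size,
                      dead_time_ms=dead_time_ms)


def burst_analysis(dwells: DwellSequence, t_crit_ms: float) -> BurstSet:
    """Group openings into bursts delimited by shut dwells > t_crit.

    Burst duration runs from the start of its first opening to the end of
    its last opening (intra-burst gaps included).
    """
    if t_crit_ms <= 0:
        raise ValueError("t_crit must be positive")
    alt = dwells.alternating()
    n_open: list[int] = []
    durs: list[float] = []
    cur_n = 0
    cur_dur = 0.0
    pending_gap = 0.0
    for d, is_open in zip(alt.durations_ms, alt.open):
        if is_open:
            if cur_n > 0:
                cur_dur += pending_gap
            pending_gap = 0.0
            cur_n += 1
            cur_dur += d
        else:
            if d > t_crit_ms:
                if cur_n:
                    n_open.append(cur_n)
                    durs.append(cur_dur)
                cur_n, cur_dur, pending_gap = 0, 0.0, 0.0
            else:
                pending_gap += d
    if cur_n:
        n_open.append(cur_n)
        durs.append(cur_dur)
    return BurstSet(t_crit_ms, np.asarray(n_open, dtype=int), np.asarray(durs))


def critical_shut_time(shut_mixture: ExpMixture, min_separation: float = 20.0,
                       quantile: float = 0.01) -> float:
    """Default critical shut time from the shut-time mixture.

    If two adjacent components are separated by at least
    ``min_separation``-fold, the equal-percent-misclassification criterion
    between them is solved.  Otherwise (a single shut component, as for
    burst-free spontaneous activity) the ``quantile`` of the fastest
    component is used, so only ~1% of genuine inter-event gaps are short
    enough to concatenate openings.
    """
    taus = np.asarray(shut_mixture.taus_ms)
    fracs = np.asarray(shut_mixture.fractions)
    if taus.size >= 2:
        ratios = taus[1:] / taus[:-1]
        k = int(np.argmax(ratios))
        if ratios[k] >= min_separation:
            t1, t2 = taus[k], taus[k + 1]
            p1, p2 = fracs[k], fracs[k + 1]

            def mis(tc):
                return p1 * np.exp(-tc / t1) - p2 * (1.0 - np.exp(-tc / t2))

            return float(brentq(mis, t1 * 1e-6, t2))
    return float(-taus[0] * np.log1p(-quantile))
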