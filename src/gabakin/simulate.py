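"""Macroscopic relaxation of a kinetic scheme under concentration-jump protocols.

The ensemble occupancy of a scheme obeys ``dp/dt = p Q(c(t))``.  Within a
protocol segment the concentration is constant, so the exact propagator is
the matrix exponential ``exp(Q dt)``; finite solution exchange at segment
boundaries is modelled as an exponential concentration relaxation with time
constant ``exchange_tau`` and integrated with sub-stepping.  Open
probability is the conductance-weighted occupancy of the open states;
macroscopic current is ``-N * i * P_open`` (inward-negative).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import expm

from .schemes import KineticScheme, q_matrix, steady_state

__all__ = [
    "ConcentrationProtocol",
    "OccupancyTrace",
    "CurrentTrace",
    "build_protocol",
    "simulate_relaxation",
    "popen_to_current",
    "simulate_overshoot",
]


@dataclass(frozen=True)
class ConcentrationProtocol:
    """Ordered ligand-concentration segments with exchange kinetics.

    ``segments`` is a sequence of ``(duration_s, {ligand: molar})``.
    ``exchange_tau_s`` smooths concentration steps at segment boundaries
    (0 = instantaneous exchange).  ``ptx_segments`` marks segments during
    which an open-channel blocker silences the conductance (occupancy
    dynamics are unchanged; only the current readout is nulled).
    """

    segments: tuple[tuple[float, Mapping[str, float]], ...]
    exchange_tau_s: float = 0.0
    label: str = ""
    ptx_segments: tuple[int, ...] = ()

    def __post_init__(self):
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        for k, (dur, conc) in enumerate(self.segments):
            if dur <= 0:
                raise ValueError(f"segment {k}: non-positive duration {dur}")
            if any(c < 0 for c in conc.values()):
                raise ValueError(f"segment {k}: negative concentration")
        if self.exchange_tau_s < 0:
            raise ValueError("exchange_tau_s must be >= 0")

    @property
    def boundaries(self) -> np.ndarray:
        """Cumulative segment end times (s), including t = 0 at the front."""
        return np.concatenate([[0.0], np.cumsum([d for d, _ in self.segments])])

    @property
    def ligands(self) -> tuple[str, ...]:
        out: dict[str, None] = {}
        for _, conc in self.segments:
            for name in conc:
                out[name] = None
        return tuple(out)


@dataclass
class OccupancyTrace:
    """Per-state occupancy probabilities on a time grid, plus P_open."""

    time_s: np.ndarray
    occupancy: np.ndarray  # (n_t, n_states)
    popen: np.ndarray
    state_names: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.occupancy.shape != (self.time_s.size, len(self.state_names)):
            raise ValueError("occupancy shape does not match time grid / states")

    def segment_window(self, k: int) -> tuple[float, float]:
        b = self.metadata["boundaries"]
        return float(b[k]), float(b[k + 1])


@dataclass
class CurrentTrace:
    """Macroscopic current (pA) on a time grid; inward currents negative."""

    time_s: np.ndarray
    current_pa: np.ndarray
    baseline_definition: str = "zero open probability"
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------


_PULSE_KINDS = {"pretreatment", "coapplication", "short_pulse", "long_pulse",
                "paired_pulse", "ptx_block", "modulator_only"}


def build_protocol(kind: str, *, agonist: str = "GABA", conc: float = 0.1,
                   pulse_s: float = 0.5, wash_pre_s: float = 0.1,
                   wash_post_s: float = 2.0, modulator: str = "FLU",
                   modulator_conc: float = 3e-6, wash_s: float = 1.0,
                   test_pulse_s: float = 0.05, ptx_s: float = 2.0,
                   exchange_tau_s: float = 0.0,
                   label: str | None = None) -> ConcentrationProtocol:
    """Construct the standard experimental protocols.

    ``pretreatment`` keeps the modulator in wash and pulse solutions (the
    initial occupancy then equilibrates with modulator present);
    ``coapplication`` adds it to the agonist pulse only.  ``paired_pulse``
    is a 500 ms conditioning pulse, a variable wash (``wash_s``), and a
    brief test pulse.  ``ptx_block`` applies an open-channel blocker to
    read out the spontaneous-activity baseline shift.
    """
    if kind not in _PULSE_KINDS:
        raise ValueError(f"unknown protocol kind {kind!r}; expected one of {sorted(_PULSE_KINDS)}")
    zero = {agonist: 0.0}
    pulse = {agonist: conc}
    if kind in ("short_pulse", "long_pulse"):
        if kind == "short_pulse" and pulse_s == 0.5:
            pulse_s = 0.005
        segs = [(wash_pre_s, zero), (pulse_s, pulse), (wash_post_s, zero)]
        ptx = ()
    elif kind == "pretreatment":
        segs = [
            (wash_pre_s, {agonist: 0.0, modulator: modulator_conc}),
            (pulse_s, {agonist: conc, modulator: modulator_conc}),
            (wash_post_s, {agonist: 0.0, modulator: modulator_conc}),
        ]
        ptx = ()
    elif kind == "coapplication":
        segs = [
            (wash_pre_s, {agonist: 0.0, modulator: 0.0}),
            (pulse_s, {agonist: conc, modulator: modulator_conc}),
            (wash_post_s, {agonist: 0.0, modulator: 0.0}),
        ]
        ptx = ()
    elif kind == "paired_pulse":
        segs = [
            (wash_pre_s, zero),
            (0.5, pulse),
            (wash_s, zero),
            (test_pulse_s, pulse),
            (wash_post_s, zero),
        ]
        ptx = ()
    elif kind == "ptx_block":
        segs = [(wash_pre_s, zero), (ptx_s, zero), (wash_post_s, zero)]
        ptx = (1,)
    else:  # modulator_only
        segs = [
            (wash_pre_s, {agonist: 0.0, modulator: 0.0}),
            (pulse_s, {agonist: 0.0, modulator: modulator_conc}),
            (wash_post_s, {agonist: 0.0, modulator: 0.0}),
        ]
        ptx = ()
    return ConcentrationProtocol(
        segments=tuple((float(d), dict(c)) for d, c in segs),
        exchange_tau_s=exchange_tau_s,
        label=label or kind,
        ptx_segments=ptx,
    )


def _fill_concentrations(conc: Mapping[str, float], ligands: Sequence[str]):
    out = {name: 0.0 for name in ligands}
    out.update(conc)
    return out


def simulate_relaxation(scheme: KineticScheme, protocol: ConcentrationProtocol,
                        p0="steady", dt: float = 1e-4,
                        max_samples_per_segment: int = 40_000,
                        exchange_substeps: int = 4) -> OccupancyTrace:
    """Propagate occupancies through a concentration protocol.

    ``p0`` is either an occupancy vector or ``"steady"`` (stationary
    distribution at the first segment's concentrations).  ``dt`` is the
    output sampling interval; segment propagation uses the exact matrix
    exponential so accuracy does not depend on ``dt`` away from exchange
    transients.  Long segments are sampled more coarsely, capped at
    ``max_samples_per_segment`` points.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = len(scheme.states)
    cw = scheme.conductance_weights

    seg_concs = [_fill_concentrations(c, protocol.ligands) for _, c in protocol.segments]
    qs = [q_matrix(scheme, c) for c in seg_concs]

    if isinstance(p0, str) and p0 == "steady":
        p = steady_state(qs[0], scheme.state_names)
    else:
        p = np.asarray(p0, dtype=float)
        if p.shape != (n,) or abs(p.sum() - 1.0) > 1e-8 or (p < -1e-12).any():
            raise ValueError("p0 must be a probability vector over the scheme's states")
        p = np.clip(p, 0.0, None)
        p = p / p.sum()

    times = [np.array([0.0])]
    occ = [p[None, :]]
    t0 = 0.0
    tau_ex = protocol.exchange_tau_s
    prev_conc = seg_concs[0]
    for k, ((duration, _), conc, Q) in enumerate(zip(protocol.segments, seg_concs, qs)):
        n_steps = max(1, int(round(duration / dt)))
        if n_steps > max_samples_per_segment:
            n_steps = max_samples_per_segment
        dt_seg = duration / n_steps
        grid = t0 + dt_seg * np.arange(1, n_steps + 1)
        seg_occ = np.empty((n_steps, n))

        smooth_until = 0
        if tau_ex > 0 and k > 0 and any(
            abs(conc[l] - prev_conc[l]) > 0 for l in protocol.ligands
        ):
            smooth_until = min(n_steps, int(np.ceil(8.0 * tau_ex / dt_seg)))

        P_const = None
        for i in range(n_steps):
            if i < smooth_until:
                # exponential solution exchange: average concentration over
                # each substep, exact propagation at that frozen value
                for j in range(exchange_substeps):
                    h = dt_seg / exchange_substeps
                    ta = i * dt_seg + j * h
                    decay = tau_ex / h * (np.exp(-ta / tau_ex) - np.exp(-(ta + h) / tau_ex))
                    c_mid = {
                        l: conc[l] + (prev_conc[l] - conc[l]) * decay
                        for l in protocol.ligands
                    }
                    p = p @ expm(q_matrix(scheme, c_mid) * h)
                    p = np.clip(p, 0.0, None)
                    p /= p.sum()
            else:
                if P_const is None:
                    P_const = expm(Q * dt_seg)
                p = p @ P_const
                p = np.clip(p, 0.0, None)
                p /= p.sum()
            seg_occ[i] = p
        times.append(grid)
        occ.append(seg_occ)
        t0 += duration
        prev_conc = conc

    time_s = np.concatenate(times)
    occupancy = np.vstack(occ)
    popen = occupancy @ cw
    boundaries = protocol.boundaries
    if protocol.ptx_segments:
        blocked = np.zeros_like(popen, dtype=bool)
        for k in protocol.ptx_segments:
            blocked |= (time_s > boundaries[k]) & (time_s <= boundaries[k + 1])
        popen = np.where(blocked, 0.0, popen)
    return OccupancyTrace(
        time_s=time_s,
        occupancy=occupancy,
        popen=popen,
        state_names=scheme.state_names,
        metadata={
            "scheme": scheme.name,
            "protocol": protocol.label,
            "boundaries": boundaries,
            "exchange_tau_s": tau_ex,
        },
    )


def popen_to_current(trace: OccupancyTrace, n_channels: int,
                     unitary_current_pa: float) -> CurrentTrace:
    """Scale open probability to whole-cell current, inward-negative.

    Display conventions that invert the sign (so that inward currents point
    up) are a plotting choice; the stored data keep the physiological sign.
    """
    if n_channels <= 0:
        raise ValueError("n_channels must be positive")
    return CurrentTrace(
        time_s=trace.time_s.copy(),
        current_pa=-float(n_channels) * float(unitary_current_pa) * trace.popen,
        baseline_definition="zero open probability",
        metadata=dict(trace.metadata, n_channels=n_channels,
                      unitary_current_pa=unitary_current_pa),
    )


def simulate_overshoot(combined_scheme: KineticScheme, *, agonist: str = "GABA",
                       conc: float = 0.1, pulse_s: float = 0.5,
                       wash_pre_s: float = 1.0, wash_post_s: float = 30.0,
                       dt: float = 2e-4) -> tuple[OccupancyTrace, dict]:
    """Agonist pulse on a scheme with both liganded and spontaneous branches.

    The pulse drives most receptors into (cross-)desensitized states and so
    depletes the spontaneously active pool: after deactivation the open
    probability dips below the pre-pulse baseline (the overshoot, in
    current space) and recovers with the resensitization time constant.

    Returns the trace and a summary with ``baseline_popen``,
    ``min_popen``, ``overshoot_amplitude`` (baseline - minimum) and
    ``resensitization_tau_s``.
    """
    spontaneous = [
        t for t in combined_scheme.transitions
        if t.order == 0 and combined_scheme.states[
            combined_scheme.state_index(t.to_state)].is_open
        and t.from_state == "R"
    ]
    if not spontaneous:
        raise ValueError(
            f"scheme {combined_scheme.name!r} has no spontaneous opening "
            "transitions from the resting state"
        )
    protocol = ConcentrationProtocol(
        segments=(
            (wash_pre_s, {agonist: 0.0}),
            (pulse_s, {agonist: conc}),
            (wash_post_s, {agonist: 0.0}),
        ),
        label="overshoot",
    )
    trace = simulate_relaxation(combined_scheme, protocol, dt=dt)
    b = protocol.boundaries
    pre = trace.time_s <= b[1]
    baseline = float(trace.popen[pre][-1])
    post = trace.time_s > b[2]
    t_post = trace.time_s[post]
    p_post = trace.popen[post]
    imin = int(np.argmin(p_post))
    minimum = float(p_post[imin])
    amplitude = baseline - minimum

    tau = np.nan
    rec_t = t_post[imin:] - t_post[imin]
    rec_y = baseline - p_post[imin:]
    if amplitude > 1e-12 and rec_t.size > 10 and rec_y[0] > 0:
        # log-linear fit over the portion still > 5% of the trough depth
        mask = rec_y > 0.05 * rec_y[0]
        if mask.sum() > 5:
            slope = np.polyfit(rec_t[mask], np.log(rec_y[mask]), 1)[0]
            if slope < 0:
                tau = -1.0 / slope
    summary = {
        "baseline_popen": baseline,
        "min_popen": minimum,
        "overshoot_amplitude": amplitude,
        "resensitization_tau_s": float(tau),
    }
    return trace, summary
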