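"""Summary statistics of macroscopic current / open-probability traces.

These are the quantities used to characterize concentration-jump
responses: 10-90% rise time of the onset, mono/bi-exponential decay fits
with the amplitude-weighted mean time constant, the fraction of the peak
remaining 10 ms and 500 ms after the peak (desensitization onset and
extent), the post-deactivation overshoot relative to baseline, the
paired-pulse recovery fraction (I2peak - I1end)/(I1peak - I1end), and the
spontaneous-activity enhancement ratio (A_PTX + A_FLU)/A_PTX.

All functions accept plain ``(time_s, value)`` arrays and apply equally to
simulated open-probability traces and to current traces read from disk.
Times are seconds on input; rise times, windows and time constants are
reported in milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize as lm_minimize

__all__ = [
    "ExpFit",
    "MetricReport",
    "rise_time_10_90",
    "fit_decay",
    "tau_mean",
    "fraction_remaining",
    "overshoot_amplitude",
    "recovery_fraction",
    "enhancement_ratio",
    "pulse_metrics",
]


@dataclass(frozen=True)
class ExpFit:
    """Sum-of-exponentials fit, amplitudes normalized to fractions."""

    fractions: tuple[float, ...]
    taus_ms: tuple[float, ...]
    constant: float = 0.0
    total_amplitude: float = 1.0
    rss: float = 0.0

    def __post_init__(self):
        if len(self.fractions) != len(self.taus_ms):
            raise ValueError("fractions and taus differ in length")
        if any(t <= 0 for t in self.taus_ms):
            raise ValueError("time constants must be positive")


@dataclass
class MetricReport:
    """Metric bundle for one trace / protocol."""

    rt_10_90_ms: float | None = None
    peak: float | None = None
    deactivation: ExpFit | None = None
    tau_mean_ms: float | None = None
    desensitization: ExpFit | None = None
    fr10: float | None = None
    fr500: float | None = None
    overshoot_amplitude: float | None = None
    recovery_fraction: float | None = None
    enhancement_ratio: float | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {}
        for key in ("rt_10_90_ms", "peak", "tau_mean_ms", "fr10", "fr500",
                    "overshoot_amplitude", "recovery_fraction",
                    "enhancement_ratio"):
            val = getattr(self, key)
            if val is not None:
                out[key] = float(val)
        for name in ("deactivation", "desensitization"):
            fit = getattr(self, name)
            if fit is not None:
                out[name] = {
                    "fractions": list(fit.fractions),
                    "taus_ms": list(fit.taus_ms),
                    "constant": fit.constant,
                }
        out.update(self.extras)
        return out


def _as_arrays(time_s, value):
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(value, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("time and value must be equal-length 1-D arrays")
    if t.size < 3:
        raise ValueError("trace too short")
    return t, y


def _first_crossing(t, y, level) -> float:
    """Time of the first crossing of ``level`` (linear interpolation)."""
    above = y >= level
    if not above.any():
        raise ValueError(f"trace never reaches level {level!r}")
    i = int(np.argmax(above))
    if i == 0:
        return float(t[0])
    frac = (level - y[i - 1]) / (y[i] - y[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def rise_time_10_90(time_s, value, baseline: float | None = None,
                    peak: float | None = None) -> float:
    """10-90% rise time (ms) of the onset, first-crossing convention.

    Invariant to amplitude scaling and time shifts.  ``baseline`` defaults
    to the first sample; ``peak`` to the extremum of |value - baseline|
    (earliest sample on ties).
    """
    t, y = _as_arrays(time_s, value)
    if baseline is None:
        baseline = float(y[0])
    y = y - baseline
    if peak is None:
        ipk = int(np.argmax(np.abs(y)))
        amp = y[ipk]
    else:
        amp = peak - baseline
    if amp == 0:
        raise ValueError("peak equals baseline; rise time undefined")
    y = y * np.sign(amp)
    amp = abs(amp)
    t10 = _first_crossing(t, y, 0.1 * amp)
    t90 = _first_crossing(t, y, 0.9 * amp)
    return (t90 - t10) * 1e3


def _exp_model(t_ms, fracs, taus, const, amp):
    comps = np.exp(-t_ms[:, None] / np.asarray(taus))
    return const + amp * comps @ np.asarray(fracs)


def fit_decay(time_s, value, n_components: int = 1,
              with_constant: bool = False, n_starts: int = 5) -> ExpFit:
    """Least-squares exponential fit of a decaying segment.

    The segment must start at its extremum.  Amplitudes are reported as
    fractions summing to 1 plus a total amplitude; for two components the
    fast time constant is listed first.  Multi-start over a deterministic
    log-spaced grid of initial time constants.
    """
    t, y = _as_arrays(time_s, value)
    if t.size < 5 * n_components:
        raise ValueError("segment too short for requested components")
    t_ms = (t - t[0]) * 1e3
    span_ms = t_ms[-1]
    y0 = y[0]
    y_end = y[-1]
    amp0 = y0 - (y_end if with_constant else 0.0)
    if amp0 == 0:
        raise ValueError("flat segment; nothing to fit")

    tau_grid = np.geomspace(max(span_ms / 200.0, 1e-4), span_ms, n_starts)

    def residual(params):
        taus = [params[f"tau{i}"].value for i in range(n_components)]
        amps = [params[f"a{i}"].value for i in range(n_components)]
        const = params["c"].value if with_constant else 0.0
        model = const + np.exp(-t_ms[:, None] / np.asarray(taus)) @ np.asarray(amps)
        return model - y

    best = None
    for s in range(n_starts):
        params = Parameters()
        base = tau_grid[s]
        for i in range(n_components):
            factor = 10.0 ** (i - (n_components - 1) / 2)
            params.add(f"tau{i}", value=base * factor, min=1e-6, max=span_ms * 100)
            params.add(f"a{i}", value=amp0 / n_components)
        if with_constant:
            params.add("c", value=y_end)
        try:
            res = lm_minimize(residual, params, method="leastsq")
        except Exception:
            continue
        rss = float(np.sum(res.residual ** 2))
        if best is None or rss < best[0]:
            best = (rss, res.params)
        if best[0] <= 1e-20 * max(1.0, float(np.sum(y ** 2))):
            break
    if best is None:
        raise RuntimeError("decay fit failed to converge from any start")
    rss, params = best
    taus = np.array([params[f"tau{i}"].value for i in range(n_components)])
    amps = np.array([params[f"a{i}"].value for i in range(n_components)])
    const = float(params["c"].value) if with_constant else 0.0
    order = np.argsort(taus)  # fast first
    taus, amps = taus[order], amps[order]
    total = amps.sum()
    if total == 0:
        raise RuntimeError("degenerate decay fit: zero total amplitude")
    return ExpFit(
        fractions=tuple(amps / total),
        taus_ms=tuple(taus),
        constant=const,
        total_amplitude=float(total),
        rss=rss,
    )


def tau_mean(fit: ExpFit) -> float:
    """Amplitude-weighted mean time constant (ms): sum A_i tau_i."""
    fracs = np.asarray(fit.fractions)
    if abs(fracs.sum() - 1.0) > 1e-6:
        raise ValueError("amplitudes must be normalized fractions summing to 1")
    return float(np.dot(fracs, fit.taus_ms))


def _peak_index(t, y, baseline, window=None):
    mask = np.ones_like(t, dtype=bool)
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        if not mask.any():
            raise ValueError("peak window outside trace")
    dev = np.abs(y - baseline)
    dev = np.where(mask, dev, -np.inf)
    return int(np.argmax(dev))  # argmax returns earliest maximum on ties


def fraction_remaining(time_s, value, window_ms: float, baseline: float = 0.0,
                       peak_window: tuple[float, float] | None = None) -> float:
    """Fraction of the (baseline-subtracted) peak remaining ``window_ms``
    after the peak sample.  Invariant to linear rescaling and baseline
    offset of the trace."""
    t, y = _as_arrays(time_s, value)
    ipk = _peak_index(t, y, baseline, peak_window)
    t_target = t[ipk] + window_ms * 1e-3
    if t_target > t[-1]:
        raise ValueError("window extends beyond the trace")
    v = float(np.interp(t_target, t, y))
    pk = y[ipk] - baseline
    if pk == 0:
        raise ValueError("zero peak amplitude")
    return float((v - baseline) / pk)


def overshoot_amplitude(time_s, value, baseline_window: tuple[float, float],
                        post_window: tuple[float, float]) -> float:
    """Baseline mean minus the post-deactivation extremum (P_open space).

    Positive when the trace dips below the pre-pulse baseline after
    deactivation (the depleted spontaneously active pool), negative when
    it has not yet returned to baseline.
    """
    t, y = _as_arrays(time_s, value)
    if baseline_window[1] >= post_window[0]:
        raise ValueError("baseline window must precede the post window")
    bmask = (t >= baseline_window[0]) & (t <= baseline_window[1])
    pmask = (t >= post_window[0]) & (t <= post_window[1])
    if not bmask.any() or not pmask.any():
        raise ValueError("windows outside trace")
    baseline = float(np.mean(y[bmask]))
    return baseline - float(np.min(y[pmask]))


def recovery_fraction(i1peak: float, i1end: float, i2peak: float) -> float:
    """Paired-pulse recovery: (I2peak - I1end)/(I1peak - I1end)."""
    denom = i1peak - i1end
    if denom == 0:
        raise ZeroDivisionError("I1peak equals I1end; recovery undefined")
    return (i2peak - i1end) / denom


def enhancement_ratio(a_flu: float, a_ptx: float) -> float:
    """Spontaneous-activity enhancement: (A_PTX + A_FLU)/A_PTX."""
    if a_ptx <= 0:
        raise ValueError("A_PTX must be positive")
    return (a_ptx + a_flu) / a_ptx


def pulse_metrics(time_s, value, pulse_window: tuple[float, float],
                  baseline: float | None = None,
                  deactivation_fit_components: int = 1,
                  desensitization_fit_components: int | None = None
                  ) -> MetricReport:
    """Standard metric bundle for a single agonist pulse.

    ``pulse_window`` is the (on, off) time of the agonist segment in
    seconds.  Baseline defaults to the mean of the pre-pulse samples.
    FR windows are anchored at the peak sample; FR500 requires the pulse
    to last at least 500 ms beyond the peak.
    """
    t, y = _as_arrays(time_s, value)
    t_on, t_off = pulse_window
    pre = t <= t_on
    if baseline is None:
        baseline = float(np.mean(y[pre])) if pre.any() else 0.0
    report = MetricReport()
    in_pulse = (t >= t_on) & (t <= t_off)
    ipk = _peak_index(t, y, baseline, (t_on, t_off))
    peak_val = float(y[ipk])
    report.peak = peak_val - baseline
    onset = (t >= t_on) & (t <= t[ipk])
    if onset.sum() >= 3:
        report.rt_10_90_ms = rise_time_10_90(t[onset], y[onset],
                                             baseline=baseline, peak=peak_val)
    t_pk = t[ipk]
    if t_off - t_pk >= 0.010:
        report.fr10 = fraction_remaining(t[in_pulse], y[in_pulse], 10.0,
                                         baseline, (t_on, t_off))
    if t_off - t_pk >= 0.5:
        report.fr500 = fraction_remaining(t[in_pulse], y[in_pulse], 500.0,
                                          baseline, (t_on, t_off))
    if desensitization_fit_components:
        seg = (t >= t_pk) & (t <= t_off)
        if seg.sum() >= 5 * desensitization_fit_components:
            try:
                report.desensitization = fit_decay(
                    t[seg], y[seg] - baseline,
                    n_components=desensitization_fit_components,
                    with_constant=True)
            except (ValueError, RuntimeError):
                pass
    post = t >= t_off
    if post.sum() >= 10:
        tp = t[post]
        yp = y[post] - baseline
        ideact = int(np.argmax(np.abs(yp)))
        seg_t, seg_y = tp[ideact:], yp[ideact:]
        if seg_y.size >= 10 and abs(seg_y[0]) > 1e-12:
            try:
                fit = fit_decay(seg_t, seg_y,
                                n_components=deactivation_fit_components)
                report.deactivation = fit
                report.tau_mean_ms = tau_mean(fit)
            except (ValueError, RuntimeError):
                pass
    return report
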