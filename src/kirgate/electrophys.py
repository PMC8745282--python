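"""Single-channel current-trace analysis.

The pipeline mirrors standard bilayer-recording practice: a zero-phase
Gaussian low-pass at the stated −3 dB cutoff, half-amplitude idealization
generalized to multiple conductance levels (nearest-level assignment with
dead-time merging), open probability as the fraction of time at any level
above baseline, all-points amplitude histograms with Gaussian-mixture level
detection, and chord conductance g = I/V (reversal at 0 mV in symmetric
KCl).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .errors import ConfigurationError, EmptyInputError, FitError

__all__ = [
    "Trace",
    "DwellSegment",
    "PoResult",
    "AmplitudeFit",
    "lowpass",
    "gaussian_rise_time",
    "idealize",
    "open_probability",
    "amplitude_histogram",
    "conductance",
    "read_trace",
    "write_trace",
]


@dataclass
class Trace:
    """A sampled current trace (pA) at fixed sampling interval (µs)."""

    dt_us: float
    current: np.ndarray
    potential_mV: float = 100.0
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.current = np.asarray(self.current, float)
        if self.dt_us <= 0:
            raise ConfigurationError("sampling interval must be positive")
        if self.current.size < 2:
            raise ConfigurationError("a trace needs at least 2 samples")

    @property
    def dt_s(self) -> float:
        return self.dt_us * 1e-6

    @property
    def duration_s(self) -> float:
        return self.current.size * self.dt_s

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.current.size) * self.dt_s


def gaussian_rise_time(cutoff_khz: float) -> float:
    """10–90% step rise time (s) of a Gaussian filter: 0.3321 / f_c."""
    return 0.3321 / (cutoff_khz * 1e3)


def lowpass(trace: Trace, cutoff_khz: float) -> Trace:
    """Zero-phase Gaussian low-pass with −3 dB point at ``cutoff_khz``.

    The impulse-response width follows the single-channel convention
    sigma_t = 0.1325 / f_c.
    """
    fc = cutoff_khz * 1e3
    nyquist = 0.5 / trace.dt_s
    if fc >= nyquist:
        raise ConfigurationError(
            f"cutoff {cutoff_khz} kHz is not below Nyquist {nyquist / 1e3:.3g} kHz"
        )
    sigma_samples = (0.1325 / fc) / trace.dt_s
    filtered = gaussian_filter1d(trace.current, sigma_samples, mode="nearest")
    meta = dict(trace.meta)
    meta["filter_khz"] = cutoff_khz
    return Trace(trace.dt_us, filtered, trace.potential_mV, trace.label, meta)


@dataclass
class DwellSegment:
    """A maximal run at one conductance level (0 = closed/baseline)."""

    level: int
    start_s: float
    duration_s: float
    mean_pA: float


def idealize(
    trace: Trace,
    baseline_pA: float = 0.0,
    unitary_pA: float = 3.6,
    n_levels: int = 1,
    dead_time_s: float | None = None,
) -> list[DwellSegment]:
    """Half-amplitude idealization generalized to multiple levels.

    Samples are assigned to the nearest level among baseline + k·unitary,
    k = 0..n_levels; contiguous equal-level runs become segments; segments
    shorter than the dead time (default: two filter rise times, when the
    trace records its filter) are merged into the neighboring segment with
    the closer level.
    """
    if unitary_pA == 0:
        raise ConfigurationError("unitary amplitude must be non-zero")
    if dead_time_s is None:
        fk = trace.meta.get("filter_khz")
        dead_time_s = 2.0 * gaussian_rise_time(fk) if fk else 0.0
    k = np.rint((trace.current - baseline_pA) / unitary_pA).astype(int)
    np.clip(k, 0, n_levels, out=k)

    # run-length encode
    change = np.flatnonzero(np.diff(k)) + 1
    starts = np.concatenate([[0], change])
    lengths = np.diff(np.concatenate([starts, [k.size]]))
    levels = k[starts]
    segs: list[list[int]] = [[int(l), int(n)] for l, n in zip(levels, lengths)]

    dead_samples = int(round(dead_time_s / trace.dt_s))

    def merge_pass(segs: list[list[int]]) -> tuple[list[list[int]], bool]:
        changed = False
        out: list[list[int]] = []
        i = 0
        while i < len(segs):
            lvl, n = segs[i]
            if n < dead_samples and len(segs) > 1:
                # merge into the neighbor with the closer level (prev on tie)
                prev_lvl = out[-1][0] if out else None
                next_lvl = segs[i + 1][0] if i + 1 < len(segs) else None
                into_prev = next_lvl is None or (
                    prev_lvl is not None and abs(prev_lvl - lvl) <= abs(next_lvl - lvl)
                )
                if into_prev and out:
                    out[-1][1] += n
                else:
                    segs[i + 1][1] += n
                changed = True
            else:
                if out and out[-1][0] == lvl:
                    out[-1][1] += n
                else:
                    out.append([lvl, n])
            i += 1
        return out, changed

    if dead_samples > 1:
        for _ in range(100):  # converges quickly; bound for safety
            segs, changed = merge_pass(segs)
            if not changed:
                break

    result: list[DwellSegment] = []
    pos = 0
    cum = np.concatenate([[0.0], np.cumsum(trace.current)])
    for lvl, n in segs:
        mean = (cum[pos + n] - cum[pos]) / n
        result.append(
            DwellSegment(
                level=lvl,
                start_s=pos * trace.dt_s,
                duration_s=n * trace.dt_s,
                mean_pA=float(mean),
            )
        )
        pos += n
    return result


@dataclass
class PoResult:
    """Open probability and per-level time occupancy."""

    po: float
    occupancy: dict[int, float]
    total_s: float


def open_probability(segments: list[DwellSegment]) -> PoResult:
    """Fraction of total time spent at any level ≥ 1."""
    if not segments:
        raise EmptyInputError("no dwell segments")
    total = sum(s.duration_s for s in segments)
    if total <= 0:
        raise EmptyInputError("zero total duration")
    occ: dict[int, float] = {}
    for s in segments:
        occ[s.level] = occ.get(s.level, 0.0) + s.duration_s
    occ = {lvl: t / total for lvl, t in sorted(occ.items())}
    po = sum(frac for lvl, frac in occ.items() if lvl >= 1)
    return PoResult(po=po, occupancy=occ, total_s=total)


@dataclass
class AmplitudeFit:
    """All-points histogram plus Gaussian-mixture level fit."""

    bin_edges: np.ndarray
    counts: np.ndarray
    means_pA: np.ndarray  # ascending
    sds_pA: np.ndarray
    weights: np.ndarray
    n_components: int


def amplitude_histogram(
    trace: Trace,
    n_bins: int = 200,
    n_levels: int | None = None,
    max_levels: int = 9,
    max_samples: int = 200_000,
    seed: int = 0,
) -> AmplitudeFit:
    """All-points amplitude histogram with Gaussian-mixture level detection.

    With ``n_levels`` given, that many components are fitted; otherwise
    1..max_levels components are scanned and the Bayesian information
    criterion selects the count.
    """
    if trace.current.size < 100:
        raise EmptyInputError("need at least 100 samples for a histogram")
    from sklearn.mixture import GaussianMixture

    counts, edges = np.histogram(trace.current, bins=n_bins)
    rng = np.random.default_rng(seed)
    data = trace.current
    if data.size > max_samples:
        data = rng.choice(data, max_samples, replace=False)
    X = data.reshape(-1, 1)

    def fit(k: int) -> GaussianMixture:
        gm = GaussianMixture(
            n_components=k,
            covariance_type="diag",
            n_init=3,
            random_state=int(rng.integers(2**31)),
            reg_covar=1e-4,
        )
        gm.fit(X)
        if not gm.converged_:
            raise FitError(f"Gaussian mixture with {k} components did not converge")
        return gm

    if n_levels is not None:
        best = fit(n_levels)
    else:
        best, best_bic = None, np.inf
        for k in range(1, max_levels + 1):
            try:
                gm = fit(k)
            except FitError:
                continue
            bic = gm.bic(X)
            if bic < best_bic - 1e-9:
                best, best_bic = gm, bic
        if best is None:
            raise FitError("no Gaussian mixture converged")

    order = np.argsort(best.means_.ravel())
    return AmplitudeFit(
        bin_edges=edges,
        counts=counts,
        means_pA=best.means_.ravel()[order],
        sds_pA=np.sqrt(best.covariances_.ravel()[order]),
        weights=best.weights_[order],
        n_components=best.n_components,
    )


def conductance(amplitude_pA: float, potential_mV: float) -> float:
    """Chord conductance in pS: 1000 · I[pA] / V[mV] (reversal at 0 mV)."""
    if potential_mV == 0:
        raise ConfigurationError("holding potential must be non-zero")
    return 1000.0 * amplitude_pA / potential_mV


# ---------------------------------------------------------------------------
# TSV input/output
# ---------------------------------------------------------------------------

def write_trace(trace: Trace, path: str | Path) -> None:
    """Two-column TSV (time_s, current_pA) with '#'-prefixed metadata."""
    with open(path, "w") as fh:
        fh.write(f"# dt_us={trace.dt_us:g}\n")
        fh.write(f"# V_mV={trace.potential_mV:g}\n")
        fh.write("time_s\tcurrent_pA\n")
        for t, c in zip(trace.times_s, trace.current):
            fh.write(f"{t:.6f}\t{c:.5f}\n")


def read_trace(path: str | Path) -> Trace:
    meta: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = float(val)
    df = pd.read_csv(path, sep="\t", comment="#")
    if "dt_us" not in meta:
        times = df["time_s"].to_numpy()
        meta["dt_us"] = float(np.median(np.diff(times)) * 1e6)
    return Trace(
        dt_us=meta["dt_us"],
        current=df["current_pA"].to_numpy(),
        potential_mV=meta.get("V_mV", 100.0),
    )
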