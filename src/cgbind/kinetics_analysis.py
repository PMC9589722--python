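"""Binding-success detection, first-passage statistics and cycle counting.

Mean first-passage times are estimated with the maximum-likelihood estimator
of an exponential waiting-time model with right censoring: trajectories that
never show the event contribute their full length to the exposure but no
event count, giving

    MFPT_hat = (sum of all durations, censored included) / (number of events)

with percentile bootstrap confidence intervals over trajectories.  Open/close
cycles of a domain are counted with two-threshold (hysteresis) segmentation
of an interdomain-distance series, which suppresses threshold chatter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class FirstPassageRecord:
    """One trajectory's event time, or its censoring time if no event."""

    duration: float
    event: bool

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")


# ---------------------------------------------------------------------------
# Binding-success rules
# ---------------------------------------------------------------------------

def binding_success(observables, rule: str = "cg_q", q_threshold: float = 0.7,
                    r_threshold: float = 3.0, theta_threshold: float = 0.4,
                    dwell: int = 10, closed_mask=None):
    """Evaluate a named binding-success rule on observable time series.

    ``observables`` is a mapping of named series (equal length):

    * rule ``cg_q``: requires every series whose name starts with ``Q``
      to be simultaneously >= ``q_threshold`` (both substrates correctly
      bound); success is stamped at the first such frame.
    * rule ``q_loose``: single series ``Q`` >= 0.4.
    * rule ``pose_rtheta``: series ``R`` (A) < ``r_threshold`` and ``theta``
      (rad) < ``theta_threshold`` sustained for ``dwell`` consecutive
      frames; success is stamped at the start of the sustained interval.
      If ``closed_mask`` is given, only frames where it is True qualify.

    Returns (success: bool, first_index: int or None).
    """
    obs = {k: np.asarray(v, dtype=float) for k, v in observables.items()}
    if rule == "cg_q":
        qs = [v for k, v in obs.items() if k.startswith("Q")]
        if not qs:
            raise ValueError("cg_q rule needs at least one Q series")
        ok = np.all([q >= q_threshold for q in qs], axis=0)
        idx = np.nonzero(ok)[0]
        return (True, int(idx[0])) if len(idx) else (False, None)
    if rule == "q_loose":
        q = obs["Q"]
        idx = np.nonzero(q >= 0.4)[0]
        return (True, int(idx[0])) if len(idx) else (False, None)
    if rule == "pose_rtheta":
        ok = (obs["R"] < r_threshold) & (obs["theta"] < theta_threshold)
        if closed_mask is not None:
            ok = ok & np.asarray(closed_mask, dtype=bool)
        if dwell < 1:
            raise ValueError("dwell must be >= 1")
        run = 0
        for i, v in enumerate(ok):
            run = run + 1 if v else 0
            if run >= dwell:
                return True, i - dwell + 1
        return False, None
    raise ValueError(f"unknown binding rule {rule!r}")


def first_passage(times, predicate_series) -> FirstPassageRecord:
    """Extract the first-passage record from a per-frame boolean series.

    ``times`` are frame times; the duration is the time of the first True
    frame (at least the first stride, so durations stay positive), or the
    trajectory length with ``event=False`` if the predicate never fires.
    """
    times = np.asarray(times, dtype=float)
    pred = np.asarray(predicate_series, dtype=bool)
    if len(times) != len(pred):
        raise ValueError("times and predicate series differ in length")
    idx = np.nonzero(pred)[0]
    total = times[-1] - times[0]
    if total <= 0:
        raise ValueError("trajectory has no extent")
    stride_dt = times[1] - times[0] if len(times) > 1 else total
    if len(idx) == 0:
        return FirstPassageRecord(duration=total, event=False)
    t = times[idx[0]] - times[0]
    return FirstPassageRecord(duration=max(t, stride_dt), event=True)


# ---------------------------------------------------------------------------
# MFPT estimation
# ---------------------------------------------------------------------------

def mfpt_mle(records, n_boot: int = 1000, ci: float = 0.95, seed: int = 0):
    """Censored-exponential MLE of the mean first-passage time.

    Returns (mfpt, (ci_low, ci_high)).  Requires at least one observed
    event.  The bootstrap resamples whole records; resamples without events
    are redrawn (they carry no likelihood information about the rate).
    """
    records = list(records)
    n_events = sum(r.event for r in records)
    if n_events == 0:
        raise ValueError("no passages observed; MFPT undefined")
    total = sum(r.duration for r in records)
    est = total / n_events
    if n_boot <= 0:
        return est, (np.nan, np.nan)
    rng = np.random.default_rng(seed)
    durations = np.array([r.duration for r in records])
    events = np.array([r.event for r in records])
    n = len(records)
    boots = []
    attempts = 0
    while len(boots) < n_boot and attempts < 50 * n_boot:
        attempts += 1
        pick = rng.integers(0, n, size=n)
        ne = events[pick].sum()
        if ne == 0:
            continue
        boots.append(durations[pick].sum() / ne)
    boots = np.array(boots)
    alpha = (1.0 - ci) / 2.0
    return est, (float(np.quantile(boots, alpha)),
                 float(np.quantile(boots, 1.0 - alpha)))


# ---------------------------------------------------------------------------
# Conformational cycle counting
# ---------------------------------------------------------------------------

def count_conformation_cycles(series, closed_threshold: float,
                              open_threshold: float,
                              until_index: int | None = None) -> int:
    """Count completed open/close round trips in a distance series.

    Two-threshold hysteresis: the domain is "closed" when the series drops
    below ``closed_threshold`` and "open" when it exceeds ``open_threshold``
    (requires closed_threshold < open_threshold for a nonzero gap; equal
    values give a single chatter-prone threshold).  One cycle is one
    completed closed->open->closed or open->closed->open round trip before
    ``until_index`` (e.g. the binding-success frame).
    """
    if closed_threshold > open_threshold:
        raise ValueError("closed_threshold must not exceed open_threshold")
    x = np.asarray(series, dtype=float)
    if until_index is not None:
        x = x[: until_index + 1]
    state = None
    flips = 0
    for v in x:
        if v < closed_threshold:
            if state == "open":
                flips += 1
            state = "closed"
        elif v > open_threshold:
            if state == "closed":
                flips += 1
            state = "open"
    return flips // 2


def hysteresis_thresholds(closed_value: float, open_value: float,
                          lo: float = 0.3, hi: float = 0.7) -> tuple[float, float]:
    """Default hysteresis pair at ``lo``/``hi`` of the closed-open gap."""
    gap = open_value - closed_value
    return closed_value + lo * gap, closed_value + hi * gap


# ---------------------------------------------------------------------------
# Contact-probability profiles
# ---------------------------------------------------------------------------

def contact_probability_profile(trajectories, contacts, progress_key: str,
                                contact_indices=None, n_bins: int = 10,
                                selector: str = "last", lam: float = 1.2,
                                in_area_key: str | None = None):
    """Per-contact formation probability along a closing-progress coordinate.

    ``trajectories`` is a list of dicts with ``frames`` (F, N, 3) arrays and
    ``observables`` (a DataFrame-like mapping with ``progress_key``).  For
    each trajectory the first or last monotone closing event is selected:
    the segment from the last local maximum (selector="last": before the
    final frame; "first": before the first frame reaching the closed value)
    down to the closed end of the progress series.  The segment is binned
    into ``n_bins`` progress quantiles (bin 0 = most open) and each native
    protein-ligand contact's formation state (r < lam * r0) is averaged over
    trajectories per bin.  Trajectories whose ligand leaves the binding area
    during the event (``in_area_key`` series False anywhere in the segment)
    are excluded.

    Returns (profile (n_contacts, n_bins), bin_centers, n_used).
    """
    if contact_indices is None:
        contact_indices = contacts.native_pairs_of_class("protein-ligand")
    contact_indices = np.asarray(contact_indices)
    if len(contact_indices) == 0:
        raise ValueError("no contacts selected")
    ci = contacts.native_i[contact_indices]
    cj = contacts.native_j[contact_indices]
    r0 = contacts.native_r0[contact_indices]

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    acc = np.zeros((len(contact_indices), n_bins))
    cnt = np.zeros(n_bins)
    n_used = 0
    for tr in trajectories:
        prog = np.asarray(tr["observables"][progress_key], dtype=float)
        frames = tr["frames"]
        seg = _closing_segment(prog, selector)
        if seg is None:
            continue
        a, b = seg
        if in_area_key is not None:
            area = np.asarray(tr["observables"][in_area_key], dtype=bool)
            if not area[a: b + 1].all():
                continue
        n_used += 1
        p = prog[a: b + 1]
        # progress 0 = most open end of the segment, 1 = fully closed
        span = p.max() - p.min()
        if span <= 0:
            continue
        prog01 = (p.max() - p) / span
        for k, f in enumerate(range(a, b + 1)):
            bin_ = min(int(prog01[k] * n_bins), n_bins - 1)
            r = np.linalg.norm(frames[f][ci] - frames[f][cj], axis=1)
            acc[:, bin_] += (r < lam * r0)
            cnt[bin_] += 1
    if n_used == 0:
        raise ValueError("no usable closing events found")
    with np.errstate(invalid="ignore"):
        prof = acc / np.where(cnt > 0, cnt, np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return prof, centers, n_used


def _closing_segment(prog, selector: str):
    """Indices (a, b) of the first or last closing sweep in a progress series.

    The series is assumed to be an opening-distance-like coordinate (large =
    open).  b is the frame where the series attains its minimum (for
    selector="first": the first frame below the 25th percentile), a the
    preceding local maximum.
    """
    prog = np.asarray(prog, dtype=float)
    if len(prog) < 3:
        return None
    if selector == "first":
        thresh = np.quantile(prog, 0.25)
        below = np.nonzero(prog <= thresh)[0]
        if len(below) == 0:
            return None
        b = int(below[0])
    elif selector == "last":
        b = int(np.argmin(prog))
    else:
        raise ValueError(f"unknown selector {selector!r}")
    if b == 0:
        return None
    a = int(np.argmax(prog[:b]))
    if a >= b:
        return None
    return a, b
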