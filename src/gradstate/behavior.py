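"""gradCPT press-to-trial assignment and response classification.

In the gradual-onset continuous performance task scenes cross-fade every
``isi`` seconds (city = go, mountain = no-go), so a button press has no
unique trial: RT is measured from the start of the transition to the current
image, and a press at RT = isi lands at the moment the image is 100%
coherent.  A press with RT in [0.7*isi, 1.4*isi] relative to some trial —
at or after 70% coherence of that scene and at or before 40% coherence of
the next — is unambiguously that trial's response.  Remaining presses sit
between two candidate trials and are resolved by an iterative algorithm that
maximises correct responses: assign to the adjacent trial without a response;
if both are free, to the closest (by full-coherence moment), except that a
no-go neighbour gets the benefit of the doubt; finally, when several presses
land on one trial, the fastest is kept.

The module also provides response classification (correct commission /
omission error on go trials, commission error / correct omission on no-go),
error counting, the "tune-out" exclusion rule (a silent gap of >= 30 s), and
a brute-force assignment oracle used to audit the iterative algorithm on
small instances.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TrialStream",
    "RTSeries",
    "rt_to_coherence",
    "assign_presses",
    "error_counts",
    "exclude_tuneouts",
    "max_correct_assignment",
    "audit_assignment",
]

logger = logging.getLogger(__name__)

#: RT window (in units of isi) within which a press belongs to a trial
#: unambiguously: [70% coherence of the scene, 40% coherence of the next].
UNAMBIG_LO = 0.7
UNAMBIG_HI = 1.4

CITY = "city"
MOUNTAIN = "mountain"


@dataclass
class TrialStream:
    """Stimulus schedule of one gradCPT run."""

    onsets: np.ndarray          # seconds; start of the transition to image n
    categories: np.ndarray      # 'city' | 'mountain' per trial
    scene_ids: np.ndarray       # scene identity per trial
    isi: float

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.categories = np.asarray(self.categories)
        self.scene_ids = np.asarray(self.scene_ids)
        if self.isi <= 0:
            raise ValueError("isi must be positive")
        if self.onsets.ndim != 1 or self.onsets.size < 1:
            raise ValueError("onsets must be a nonempty 1-D array")
        if not (self.categories.shape == self.onsets.shape == self.scene_ids.shape):
            raise ValueError("onsets, categories and scene_ids must align")
        d = np.diff(self.onsets)
        if d.size and not np.allclose(d, self.isi, atol=1e-9):
            raise ValueError("onsets must be evenly spaced at isi")
        if np.any(self.scene_ids[1:] == self.scene_ids[:-1]):
            raise ValueError("consecutive trials must not repeat a scene")

    @property
    def n_trials(self) -> int:
        return self.onsets.size

    def is_city(self) -> np.ndarray:
        return self.categories == CITY


@dataclass
class RTSeries:
    """Per-trial assigned RTs and response classifications."""

    rts: np.ndarray                 # seconds, NaN when no press assigned
    classification: np.ndarray      # one of the four response classes
    assigned_press: np.ndarray      # raw press index, -1 when absent
    press_times: np.ndarray         # the raw press timestamps (for gap checks)
    isi: float
    onsets: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.rts.size

    def responded(self) -> np.ndarray:
        return ~np.isnan(self.rts)


def rt_to_coherence(rt: float, isi: float) -> tuple[float, float]:
    """Split an RT into (current-image fraction, neighbour-image fraction).

    During the linear cross-fade, a press at RT <= isi sees the current image
    at rt/isi coherence mixed with the previous image; for isi < RT <= 2*isi
    the current image is fading out at 2 - rt/isi against the next.
    """
    if isi <= 0:
        raise ValueError("isi must be positive")
    if not 0.0 <= rt <= 2.0 * isi:
        raise ValueError(f"rt {rt} outside [0, 2*isi]")
    if rt <= isi:
        return rt / isi, 1.0 - rt / isi
    return 2.0 - rt / isi, rt / isi - 1.0


def _press_geometry(press: float, stream: TrialStream) -> tuple[int | None, list[int]]:
    """(unambiguous trial or None, adjacent candidate trials) for one press.

    A press between the full-coherence moments of trials n-1 and n (where
    n = floor((press - first onset)/isi)) is adjacent to exactly those two
    trials: RT relative to n is in [0, isi), relative to n-1 in [isi, 2*isi).
    It is unambiguous for n when RT_n >= 0.7*isi, unambiguous for n-1 when
    RT_{n-1} <= 1.4*isi; otherwise (RT_n strictly inside (0.4, 0.7)*isi) it
    is ambiguous between the two.  Out-of-stream neighbours are dropped.
    """
    isi = stream.isi
    t0 = stream.onsets[0]
    if press < t0:
        return None, []
    n = int(np.floor((press - t0) / isi + 1e-12))
    cands = [t for t in (n - 1, n) if 0 <= t < stream.n_trials
             and 0.0 <= press - stream.onsets[t] <= 2.0 * isi]
    if not cands:
        return None, []
    unambig: int | None = None
    for t in cands:
        rt = press - stream.onsets[t]
        if UNAMBIG_LO * isi - 1e-12 <= rt <= UNAMBIG_HI * isi + 1e-12:
            unambig = t
            break
    return unambig, cands


def assign_presses(stream: TrialStream, presses: Sequence[float]) -> RTSeries:
    """Assign raw presses to trials, maximising correct responses.

    Three passes: (1) presses in the unambiguous window [0.7*isi, 1.4*isi]
    stay with their trial, the fastest per trial taking the slot (surplus
    presses join the ambiguous pool, mirroring the multiple-press rule);
    (2) each remaining press goes to the adjacent trial without a response —
    if both are free, to the closest by distance to the full-coherence
    moment (onset + isi; ties to the earlier trial), except that a free
    no-go (mountain) neighbour is given the benefit of the doubt and left
    unassigned; pass 2 repeats to a fixed point since an assignment can
    resolve a neighbour's ambiguity; (3) any press still contending for an
    occupied trial is dropped (the fastest already holds the slot).
    """
    presses = np.asarray(presses, dtype=float)
    if presses.size > 1 and np.any(np.diff(presses) < 0):
        raise ValueError("presses must be sorted ascending")

    n_trials = stream.n_trials
    geo = [_press_geometry(p, stream) for p in presses]
    assigned = np.full(presses.size, -1, dtype=int)   # press -> trial
    holder = np.full(n_trials, -1, dtype=int)         # trial -> press

    # pass 1: unambiguous presses; fastest per trial keeps the slot
    for t in range(n_trials):
        owners = [i for i, (u, _) in enumerate(geo) if u == t]
        if owners:
            rts_t = [presses[i] - stream.onsets[t] for i in owners]
            keep = owners[int(np.argmin(rts_t))]
            assigned[keep] = t
            holder[t] = keep

    # pass 2: remaining presses (ambiguous or surplus), to a fixed point
    floating = [i for i in range(presses.size) if assigned[i] < 0 and geo[i][1]]
    for _ in range(max(presses.size, 1)):
        changed = False
        for i in floating:
            if assigned[i] >= 0:
                continue
            unambig_i, cands = geo[i]
            free = [t for t in cands if holder[t] < 0]
            target = -1
            if len(free) == 1:
                target = free[0]
                if (
                    len(cands) == 1
                    and unambig_i is None
                    and stream.categories[target] == MOUNTAIN
                ):
                    # run-boundary ambiguous press next to a lone free no-go:
                    # benefit of the doubt, leave the mountain unpressed
                    target = -1
            elif len(free) == 2:
                a, b = free
                a_mountain = stream.categories[a] == MOUNTAIN
                b_mountain = stream.categories[b] == MOUNTAIN
                if a_mountain and not b_mountain:
                    target = b
                elif b_mountain and not a_mountain:
                    target = a
                elif a_mountain and b_mountain:
                    target = -1   # both no-go: benefit of the doubt to both
                else:
                    da = abs(presses[i] - (stream.onsets[a] + stream.isi))
                    db = abs(presses[i] - (stream.onsets[b] + stream.isi))
                    target = a if da <= db else b
            if target >= 0:
                assigned[i] = target
                holder[target] = i
                changed = True
        if not changed:
            break

    # pass 3: collect per-trial RTs (slots already hold a single press each)
    rts = np.full(n_trials, np.nan)
    for t in range(n_trials):
        if holder[t] >= 0:
            rts[t] = presses[holder[t]] - stream.onsets[t]
    chosen = holder

    classification = np.where(
        stream.is_city(),
        np.where(~np.isnan(rts), "correct_commission", "omission_error"),
        np.where(~np.isnan(rts), "commission_error", "correct_omission"),
    )
    return RTSeries(
        rts=rts,
        classification=classification,
        assigned_press=chosen,
        press_times=presses,
        isi=stream.isi,
        onsets=stream.onsets,
    )


def error_counts(rts: RTSeries, categories: np.ndarray | None = None) -> dict:
    """Counts and rates of the four response classes.

    Omission rate is over go (city) trials, commission rate over no-go
    (mountain) trials.
    """
    cls = rts.classification
    n_omission = int(np.sum(cls == "omission_error"))
    n_commission = int(np.sum(cls == "commission_error"))
    n_cc = int(np.sum(cls == "correct_commission"))
    n_co = int(np.sum(cls == "correct_omission"))
    n_city = n_cc + n_omission
    n_mountain = n_co + n_commission
    return {
        "omission_errors": n_omission,
        "commission_errors": n_commission,
        "correct_commissions": n_cc,
        "correct_omissions": n_co,
        "omission_rate": n_omission / n_city if n_city else float("nan"),
        "commission_rate": n_commission / n_mountain if n_mountain else float("nan"),
    }


def exclude_tuneouts(rts: RTSeries, window: float = 30.0) -> bool:
    """Flag a run with a response gap of ``window`` seconds or more.

    Gaps are measured between consecutive assigned presses and against the
    run boundaries (first onset, last onset + isi); a gap exactly equal to
    the window counts ("30 s or more").  Flagged participants are excluded
    from population analyses.
    """
    responded = rts.responded()
    times = rts.onsets[responded] + rts.rts[responded]
    start = rts.onsets[0]
    end = rts.onsets[-1] + rts.isi
    points = np.concatenate([[start], np.sort(times), [end]])
    return bool(np.max(np.diff(points)) >= window)


# ---------------------------------------------------------------------------
# brute-force oracle (small instances only)


def max_correct_assignment(stream: TrialStream, presses: Sequence[float]) -> int:
    """Maximum number of correct responses over all valid assignments.

    Exhaustively enumerates assignments of presses to candidate trials and
    counts go trials with a response plus no-go trials without one, subject
    to the same validity rules the iterative algorithm obeys: at most one
    press per trial; a press in a trial's unambiguous window may move to
    its other adjacent trial only when its own trial is taken by another
    press; and a press may stay unassigned only when every remaining
    candidate is occupied or is a no-go trial reachable only ambiguously
    (the benefit-of-the-doubt freedom).  Exponential in the number of
    presses; intended for instances with <= ~8 presses.
    """
    presses = np.asarray(presses, dtype=float)
    geo = [_press_geometry(p, stream) for p in presses]
    is_city = stream.is_city()
    n_mountain_total = int(np.sum(~is_city))
    best = 0
    for choice in itertools.product(*[g[1] + [None] for g in geo]):
        used = [t for t in choice if t is not None]
        if len(used) != len(set(used)):
            continue
        occupied = set(used)
        ok = True
        for i, t in enumerate(choice):
            unambig, cands = geo[i]
            if t is None:
                for c in cands:
                    if c in occupied:
                        continue
                    if unambig is None and not is_city[c]:
                        continue   # ambiguous press sparing a free no-go
                    ok = False     # a legitimate free slot was ignored
                    break
                if not ok:
                    break
            elif unambig is not None and t != unambig and unambig not in occupied:
                ok = False         # moved off a free unambiguous home trial
                break
        if not ok:
            continue
        correct = sum(1 for t in occupied if is_city[t])
        correct += n_mountain_total - sum(1 for t in occupied if not is_city[t])
        best = max(best, correct)
    return best


def audit_assignment(stream: TrialStream, presses: Sequence[float]) -> dict:
    """Compare the iterative algorithm against the brute-force maximum.

    Returns the achieved and optimal correct-response counts plus a
    ``shortfall`` flag; any shortfall is logged so that greedy-vs-optimal
    discrepancies are reported rather than silently absorbed.
    """
    series = assign_presses(stream, presses)
    counts = error_counts(series)
    achieved = counts["correct_commissions"] + counts["correct_omissions"]
    optimal = max_correct_assignment(stream, presses)
    shortfall = optimal - achieved
    if shortfall > 0:
        logger.warning(
            "press assignment achieved %d correct vs optimal %d "
            "(trials=%d, presses=%d)",
            achieved, optimal, stream.n_trials, len(presses),
        )
    return {
        "achieved": achieved,
        "optimal": optimal,
        "shortfall": shortfall,
        "series": series,
    }
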