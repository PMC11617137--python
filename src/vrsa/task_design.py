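"""Factorial reach-task design: trial types, board geometry, timed runs,
HRF-convolved GLM design matrices, and VIF-based design optimization.

The task is a 2x2x2 factorial delayed reach-to-target paradigm: initial hand
position (H), target position (T), and instructed gaze position (E) are each
on the left or the right of a task board.  Side combinations induce derived
near/far "distance" levels for the hand-target (HT), gaze-target (ET) and
hand-gaze (HE) vectors.  Each functional run is a timed sequence of 40 trials
(5 per trial type) with variable delay and plan durations and a 60/40 go/no-go
split; trial order and timing are chosen to minimize the variance inflation
factor (VIF) of the condition regressors in the planning-epoch GLMs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "BoardGeometry",
    "TrialType",
    "TrialTiming",
    "RunDesign",
    "DesignMatrix",
    "CollinearityError",
    "enumerate_trial_types",
    "board_distances",
    "largest_remainder_counts",
    "sample_run",
    "canonical_hrf",
    "build_design_matrix",
    "build_generative_matrix",
    "vif",
    "optimize_design",
]

LEFT, RIGHT = -1, 1
SIDE_LABEL = {LEFT: "L", RIGHT: "R"}

#: Delay between hand/gaze instruction and target onset, seconds, with the
#: fraction of trials at each level.
DELAY_LEVELS_S = (1.0, 2.0, 4.0, 8.0, 16.0)
DELAY_PROPORTIONS = (0.52, 0.26, 0.13, 0.06, 0.03)

#: Target illumination (planning) duration, seconds, with trial fractions.
PLAN_LEVELS_S = (4.0, 6.0, 8.0)
PLAN_PROPORTIONS = (0.56, 0.30, 0.14)

N_TRIALS_PER_RUN = 40
N_TRIALS_PER_TYPE = 5
GO_PER_TYPE = 3  # 3 go + 2 no-go per type -> exactly 60% go, >=2 no-go events per condition
TR_S = 0.45
EPOCH_S = 2.0  # early/late planning epochs modeled as 2 s boxcars

FEEDBACK_S = 2.5  # feedback cue window after the go/no-go cue on no-go trials
GAP_S = 1.0  # interval between feedback and the next trial
MOVEMENT_S = 1.0  # nominal reach duration modeled on go trials
RUN_TAIL_S = 20.0  # padding after the last trial so the HRF can return to baseline


class CollinearityError(np.linalg.LinAlgError):
    """Raised when the task regressors are linearly dependent."""


@dataclass(frozen=True)
class BoardGeometry:
    """LED separations (cm) on the task board.

    All six LEDs are collinear and symmetric about the board center, so each
    element's position is ``+/- separation / 2``.
    """

    hand_sep: float = 2.3
    target_sep: float = 6.9
    gaze_sep: float = 32.9

    def __post_init__(self) -> None:
        if min(self.hand_sep, self.target_sep, self.gaze_sep) <= 0:
            raise ValueError("LED separations must be positive")
        if not (self.gaze_sep > self.target_sep > self.hand_sep):
            raise ValueError("expected gaze_sep > target_sep > hand_sep")

    def position(self, element: str, side: int) -> float:
        sep = {"H": self.hand_sep, "T": self.target_sep, "E": self.gaze_sep}[element]
        return side * sep / 2.0


@dataclass(frozen=True)
class TrialType:
    """One of the 8 hand/target/gaze side combinations.

    Sides are coded -1 (left) / +1 (right).  The derived near/far levels
    follow from side equality: a pair is *near* iff its two elements share a
    side.
    """

    hand_side: int
    target_side: int
    gaze_side: int

    def __post_init__(self) -> None:
        for s in (self.hand_side, self.target_side, self.gaze_side):
            if s not in (LEFT, RIGHT):
                raise ValueError("sides must be coded -1 (left) or +1 (right)")

    @property
    def ht_level(self) -> str:
        return "near" if self.hand_side == self.target_side else "far"

    @property
    def et_level(self) -> str:
        return "near" if self.gaze_side == self.target_side else "far"

    @property
    def he_level(self) -> str:
        return "near" if self.hand_side == self.gaze_side else "far"

    @property
    def label(self) -> str:
        """H-T-E side label, e.g. ``"L-R-L"``."""
        return "-".join(
            SIDE_LABEL[s] for s in (self.hand_side, self.target_side, self.gaze_side)
        )


def enumerate_trial_types() -> list[TrialType]:
    """The 8 trial types in canonical lexicographic (hand, target, gaze) order."""
    return [
        TrialType(h, t, e)
        for h, t, e in itertools.product((LEFT, RIGHT), repeat=3)
    ]


CONDITION_LABELS = tuple(t.label for t in enumerate_trial_types())


def board_distances(geometry: BoardGeometry | None = None) -> dict[tuple[str, str], float]:
    """Pairwise element distances (cm) for same-side and opposite-side layouts.

    Returns a mapping ``{(pair, config): cm}`` with ``pair`` in
    ``{"ET", "HT", "HE"}`` and ``config`` in ``{"same", "opposite"}``.  Because
    the separations are nested (gaze > target > hand), the same-side distance
    is always the *near* level of the corresponding factor.
    """
    g = geometry if geometry is not None else BoardGeometry()
    pairs = {"ET": ("E", "T"), "HT": ("H", "T"), "HE": ("H", "E")}
    out: dict[tuple[str, str], float] = {}
    for name, (a, b) in pairs.items():
        for config, side_b in (("same", RIGHT), ("opposite", LEFT)):
            d = abs(g.position(a, RIGHT) - g.position(b, side_b))
            out[(name, config)] = round(d, 10)
    return out


def distance_levels(geometry: BoardGeometry | None = None) -> dict[tuple[str, str], float]:
    """Distances keyed by ``(pair, "near"/"far")`` instead of board layout."""
    d = board_distances(geometry)
    return {
        (pair, {"same": "near", "opposite": "far"}[config]): cm
        for (pair, config), cm in d.items()
    }


@dataclass(frozen=True)
class TrialTiming:
    """Event times for one trial, seconds from run start."""

    onset_s: float
    delay_s: float
    plan_s: float
    go: bool

    def __post_init__(self) -> None:
        if self.delay_s not in DELAY_LEVELS_S:
            raise ValueError(f"delay_s must be one of {DELAY_LEVELS_S}")
        if self.plan_s not in PLAN_LEVELS_S:
            raise ValueError(f"plan_s must be one of {PLAN_LEVELS_S}")

    @property
    def target_onset_s(self) -> float:
        return self.onset_s + self.delay_s

    @property
    def cue_s(self) -> float:
        """Go/no-go auditory cue time (end of the planning period)."""
        return self.target_onset_s + self.plan_s

    @property
    def end_s(self) -> float:
        post = MOVEMENT_S + GAP_S if self.go else FEEDBACK_S + GAP_S
        return self.cue_s + post


@dataclass(frozen=True)
class RunDesign:
    """An ordered, timed 40-trial functional run."""

    trials: tuple[tuple[TrialType, TrialTiming], ...]
    tr_s: float = TR_S

    @property
    def n_scans(self) -> int:
        return int(math.ceil((self.trials[-1][1].end_s + RUN_TAIL_S) / self.tr_s))

    @property
    def duration_s(self) -> float:
        return self.n_scans * self.tr_s

    def validate(self) -> None:
        if len(self.trials) != N_TRIALS_PER_RUN:
            raise ValueError(f"expected {N_TRIALS_PER_RUN} trials")
        counts: dict[str, int] = {}
        go_count = 0
        for ttype, timing in self.trials:
            counts[ttype.label] = counts.get(ttype.label, 0) + 1
            go_count += timing.go
        if sorted(counts.values()) != [N_TRIALS_PER_TYPE] * 8:
            raise ValueError("expected 5 trials of each of the 8 types")
        if go_count != GO_PER_TYPE * 8:
            raise ValueError("expected exactly 24 go trials (60%)")

    def to_dict(self) -> dict:
        return {
            "tr_s": self.tr_s,
            "n_scans": self.n_scans,
            "trials": [
                {
                    "type": t.label,
                    "hand_side": t.hand_side,
                    "target_side": t.target_side,
                    "gaze_side": t.gaze_side,
                    "onset_s": tm.onset_s,
                    "delay_s": tm.delay_s,
                    "plan_s": tm.plan_s,
                    "go": tm.go,
                }
                for t, tm in self.trials
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunDesign":
        trials = tuple(
            (
                TrialType(tr["hand_side"], tr["target_side"], tr["gaze_side"]),
                TrialTiming(tr["onset_s"], tr["delay_s"], tr["plan_s"], tr["go"]),
            )
            for tr in d["trials"]
        )
        return cls(trials=trials, tr_s=d.get("tr_s", TR_S))


def largest_remainder_counts(proportions, n: int, levels=None) -> list[int]:
    """Integer counts for ``proportions * n`` by the largest-remainder method.

    Remainder ties are broken in favor of the rarer level (smaller integer
    base count), then the earlier (shorter-duration) level.
    """
    props = np.asarray(proportions, dtype=float)
    if not np.isclose(props.sum(), 1.0):
        raise ValueError("proportions must sum to 1")
    exact = props * n
    counts = np.floor(np.round(exact, 9)).astype(int)
    # Round remainders so that exact ties in the underlying rationals are not
    # broken by floating-point noise (0.26*40 vs 0.06*40 both leave 0.4).
    remainders = np.round(exact - counts, 9)
    order = sorted(
        range(len(props)),
        key=lambda i: (-remainders[i], counts[i], i),
    )
    for i in order[: n - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


def _level_sequence(levels, proportions, n: int, rng: np.random.Generator) -> list[float]:
    counts = largest_remainder_counts(proportions, n)
    seq = [lvl for lvl, c in zip(levels, counts) for _ in range(c)]
    return [seq[i] for i in rng.permutation(n)]


def sample_run(rng_seed: int | np.random.Generator) -> RunDesign:
    """Draw one randomized run respecting the printed trial composition.

    Exact counts, not sampling: 5 trials per type with 3 go / 2 no-go each,
    and delay/plan duration counts fixed by largest-remainder rounding of the
    stated proportions.  Only the assignment of durations, go labels and the
    trial order are random.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    types = enumerate_trial_types()
    slots: list[tuple[TrialType, bool]] = []
    for t in types:
        labels = [True] * GO_PER_TYPE + [False] * (N_TRIALS_PER_TYPE - GO_PER_TYPE)
        slots.extend((t, bool(g)) for g in rng.permutation(labels))
    slots = [slots[i] for i in rng.permutation(len(slots))]

    delays = _level_sequence(DELAY_LEVELS_S, DELAY_PROPORTIONS, N_TRIALS_PER_RUN, rng)
    plans = _level_sequence(PLAN_LEVELS_S, PLAN_PROPORTIONS, N_TRIALS_PER_RUN, rng)

    trials = []
    onset = 0.0
    for (ttype, go), delay, plan in zip(slots, delays, plans):
        timing = TrialTiming(onset_s=onset, delay_s=delay, plan_s=plan, go=go)
        trials.append((ttype, timing))
        onset = timing.end_s
    run = RunDesign(trials=tuple(trials))
    run.validate()
    return run


# ---------------------------------------------------------------------------
# HRF convolution and design matrices
# ---------------------------------------------------------------------------

_HRF_DT = 0.05  # microtime resolution for convolution, seconds (TR/9)


def canonical_hrf(t: np.ndarray, peak_delay: float = 6.0, undershoot_delay: float = 16.0,
                  peak_disp: float = 1.0, undershoot_disp: float = 1.0,
                  ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, peak normalized to 1.

    Difference of two gamma densities (response minus a 1/``ratio``-weighted
    undershoot); with the defaults the response peaks ~5 s after the impulse.
    """
    t = np.asarray(t, dtype=float)
    h = stats.gamma.pdf(t, peak_delay / peak_disp, scale=peak_disp) - (
        stats.gamma.pdf(t, undershoot_delay / undershoot_disp, scale=undershoot_disp)
        / ratio
    )
    peak = h.max()
    return h / peak if peak > 0 else h


@dataclass(frozen=True)
class DesignMatrix:
    """HRF-convolved regressors sampled at the scan times.

    ``task`` flags the columns whose estimation variance enters the VIF (the
    8 no-go condition regressors and the pooled go-trial planning regressor);
    movement and the constant are modeled but excluded from the VIF.
    """

    values: np.ndarray  # (n_scans, n_columns)
    names: tuple[str, ...]
    task: tuple[bool, ...]
    epoch: str
    tr_s: float = TR_S

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.names) or len(self.names) != len(self.task):
            raise ValueError("column metadata does not match matrix width")
        if len(set(self.names)) != len(self.names):
            raise ValueError("column names must be unique")

    @property
    def condition_columns(self) -> list[int]:
        return [i for i, n in enumerate(self.names) if n in CONDITION_LABELS]

    def task_values(self) -> np.ndarray:
        idx = [i for i, f in enumerate(self.task) if f]
        return self.values[:, idx]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, columns=list(self.names))


def _epoch_window(timing: TrialTiming, epoch: str) -> tuple[float, float]:
    if epoch == "early":
        return timing.target_onset_s, timing.target_onset_s + EPOCH_S
    if epoch == "late":
        return timing.cue_s - EPOCH_S, timing.cue_s
    raise ValueError(f"unknown epoch {epoch!r}; expected 'early' or 'late'")


def _convolve_events(events: dict[str, list[tuple[float, float]]], n_scans: int,
                     tr_s: float) -> dict[str, np.ndarray]:
    """Boxcars on half-open [on, off) intervals -> HRF-convolved scan samples."""
    duration = n_scans * tr_s
    n_fine = int(math.ceil(duration / _HRF_DT)) + 1
    t_fine = np.arange(n_fine) * _HRF_DT
    hrf = canonical_hrf(np.arange(0.0, 32.0, _HRF_DT))
    scan_idx = np.round(np.arange(n_scans) * tr_s / _HRF_DT).astype(int)
    out = {}
    for name, windows in events.items():
        box = np.zeros(n_fine)
        for on, off in windows:
            i0 = int(round(on / _HRF_DT))
            i1 = int(round(off / _HRF_DT))
            box[i0:min(i1, n_fine)] = 1.0
        conv = np.convolve(box, hrf)[:n_fine] * _HRF_DT
        out[name] = conv[scan_idx]
    return out


def build_design_matrix(run: RunDesign, epoch: str) -> DesignMatrix:
    """GLM design for one planning epoch of one run.

    Each no-go trial contributes a 2 s boxcar — at target onset (``early``) or
    ending at the go/no-go cue (``late``) — to its condition's regressor.
    Go-trial planning (same epoch window) and go-trial movement are modeled as
    nuisance regressors; a constant column closes the model.
    """
    if epoch not in ("early", "late"):
        raise ValueError(f"unknown epoch {epoch!r}; expected 'early' or 'late'")
    events: dict[str, list[tuple[float, float]]] = {lbl: [] for lbl in CONDITION_LABELS}
    events["go_plan"] = []
    events["movement"] = []
    for ttype, timing in run.trials:
        window = _epoch_window(timing, epoch)
        if timing.go:
            events["go_plan"].append(window)
            events["movement"].append((timing.cue_s, timing.cue_s + MOVEMENT_S))
        else:
            events[ttype.label].append(window)
    cols = _convolve_events(events, run.n_scans, run.tr_s)
    names = list(CONDITION_LABELS) + ["go_plan", "movement", "constant"]
    task = [True] * 8 + [True, False, False]
    values = np.column_stack(
        [cols[n] for n in names[:-1]] + [np.ones(run.n_scans)]
    )
    return DesignMatrix(values=values, names=tuple(names), task=tuple(task), epoch=epoch)


def build_generative_matrix(run: RunDesign) -> DesignMatrix:
    """Design containing both epochs' condition regressors simultaneously.

    Used as generative truth when simulating BOLD: columns are
    ``early:<label>`` and ``late:<label>`` per condition plus movement and a
    constant, so epoch-specific signal can be planted without model mismatch.
    """
    events: dict[str, list[tuple[float, float]]] = {}
    for ep in ("early", "late"):
        for lbl in CONDITION_LABELS:
            events[f"{ep}:{lbl}"] = []
    events["movement"] = []
    for ttype, timing in run.trials:
        if timing.go:
            events["movement"].append((timing.cue_s, timing.cue_s + MOVEMENT_S))
        else:
            for ep in ("early", "late"):
                events[f"{ep}:{ttype.label}"].append(_epoch_window(timing, ep))
    cols = _convolve_events(events, run.n_scans, run.tr_s)
    names = list(cols.keys()) + ["constant"]
    values = np.column_stack([cols[n] for n in cols] + [np.ones(run.n_scans)])
    task = [not n.startswith(("movement", "constant")) for n in names]
    return DesignMatrix(values=values, names=tuple(names), task=tuple(task), epoch="both")


def vif(X: DesignMatrix) -> float:
    """Mean variance inflation factor of the task regressors.

    For the task-column Gram matrix ``A``, the VIF of regressor *i* is
    ``inv(A)[i, i] * A[i, i]`` — its estimation variance in the joint model
    relative to estimating it in isolation — and the design's VIF is the mean
    over task regressors.  Equals 1 iff the task columns are orthogonal.
    """
    Xt = X.task_values()
    A = Xt.T @ Xt
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[0]:
        task_names = [n for n, f in zip(X.names, X.task) if f]
        # Rank-revealing QR: the trailing pivoted columns are the dependent ones.
        from scipy.linalg import qr

        _, _, piv = qr(Xt, mode="economic", pivoting=True)
        dependent = sorted(task_names[i] for i in piv[rank:])
        raise CollinearityError(
            f"task regressors are collinear; dependent columns: {dependent}"
        )
    return float(np.mean(np.diag(np.linalg.inv(A)) * np.diag(A)))


def optimize_design(
    n_candidates: int,
    rng_seed: int = 0,
    epochs: tuple[str, ...] = ("early", "late"),
    vif_bound: float = 1.15,
) -> tuple[RunDesign, float, bool]:
    """Best-of-``n_candidates`` random search minimizing the worse-epoch VIF.

    Candidate runs are drawn from :func:`sample_run` on independent child
    streams of ``rng_seed`` (so the first *k* candidates are identical across
    calls with different ``n_candidates``).  Returns ``(best_run, best_vif,
    achieved)`` where ``achieved`` reports whether ``best_vif < vif_bound``.
    """
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    children = np.random.SeedSequence(rng_seed).spawn(n_candidates)
    best_run, best_score = None, np.inf
    for child in children:
        run = sample_run(np.random.default_rng(child))
        score = max(vif(build_design_matrix(run, ep)) for ep in epochs)
        if score < best_score:
            best_run, best_score = run, score
    return best_run, best_score, best_score < vif_bound
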