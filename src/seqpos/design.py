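"""Experiment-design generation for a sequence short-term-memory task.

One scanning run consists of trials in which one to three pictures (houses or
faces) are shown one after another (presentation phase); on a subset of trials
the sequence is replayed (recognition phase) and the participant judges whether
the order was unchanged.  Item identities within a stimulus set are abstract
labels A/B/C — no images are rendered.

The module also implements the regressor bookkeeping used before GLM
estimation: every displayed item is an :class:`EventOccurrence` labelled by
(stimulus set, identity, position, phase), and occurrences sharing a label are
combined in groups of ``n`` into single event regressors, spread out in time so
that a regressor's members do not cluster.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STIMULUS_SETS = ("houses", "faces")
IDENTITIES = ("A", "B", "C")
PHASES = ("presentation", "recognition")

#: Default length distribution: fractions of 3-, 2- and 1-item sequences.
DEFAULT_LENGTH_DISTRIBUTION: Mapping[int, float] = {3: 0.44, 2: 0.39, 1: 0.17}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Trial:
    """A single trial: presentation of a short sequence, optionally probed."""

    index: int
    stimulus_set: str
    length: int
    item_order: tuple[str, ...]
    has_recognition: bool
    probe_changed: bool
    probe_order: tuple[str, ...]
    onset_s: float
    rest_s: float
    item_duration_s: float = 3.5
    post_sequence_delay_s: float = 2.0

    def __post_init__(self):
        if len(set(self.item_order)) != len(self.item_order):
            raise ValueError("item_order contains a repeated identity")
        if len(self.item_order) != self.length:
            raise ValueError("item_order length does not match trial length")
        if self.probe_changed and not self.has_recognition:
            raise ValueError("probe_changed implies has_recognition")
        if self.has_recognition and sorted(self.probe_order) != sorted(self.item_order):
            raise ValueError("probe must replay the same items")

    @property
    def presentation_onsets(self) -> tuple[float, ...]:
        return tuple(self.onset_s + i * self.item_duration_s for i in range(self.length))

    @property
    def recognition_start_s(self) -> float:
        return self.onset_s + self.length * self.item_duration_s + self.post_sequence_delay_s

    @property
    def recognition_onsets(self) -> tuple[float, ...]:
        if not self.has_recognition:
            return ()
        start = self.recognition_start_s
        return tuple(start + i * self.item_duration_s for i in range(self.length))

    @property
    def end_s(self) -> float:
        """Time at which the post-trial rest period ends."""
        t = self.onset_s + self.length * self.item_duration_s + self.post_sequence_delay_s
        if self.has_recognition:
            t += self.length * self.item_duration_s
        return t + self.rest_s


@dataclass
class ExperimentDesign:
    """Full trial/event schedule of one participant's scanning run."""

    trials: list[Trial]
    tr_s: float = 1.75
    n_volumes: int = 0

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def length_counts(self) -> dict[int, int]:
        return dict(Counter(t.length for t in self.trials))

    @property
    def probed_fraction(self) -> float:
        if not self.trials:
            return 0.0
        return sum(t.has_recognition for t in self.trials) / self.n_trials

    @property
    def n_changed_probes(self) -> int:
        return sum(t.probe_changed for t in self.trials)

    @property
    def duration_s(self) -> float:
        return self.n_volumes * self.tr_s

    def validate(self) -> None:
        prev_end = -np.inf
        for t in self.trials:
            if t.onset_s < prev_end - 1e-9:
                raise ValueError(f"trial {t.index} overlaps the previous trial")
            prev_end = t.end_s
        if self.trials and self.trials[-1].end_s > self.duration_s + 1e-9:
            raise ValueError("schedule extends beyond the scanned volumes")

    # -- serialization ------------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "tr_s": self.tr_s,
            "n_volumes": self.n_volumes,
            "trials": [asdict(t) for t in self.trials],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ExperimentDesign":
        payload = json.loads(text)
        trials = []
        for d in payload["trials"]:
            d["item_order"] = tuple(d["item_order"])
            d["probe_order"] = tuple(d["probe_order"])
            trials.append(Trial(**d))
        return cls(trials=trials, tr_s=payload["tr_s"], n_volumes=payload["n_volumes"])


@dataclass(frozen=True)
class EventOccurrence:
    """One displayed item in one phase of one trial.

    ``position`` is the *displayed* position (for changed probes the replayed
    position may differ from the originally presented one, in which case the
    occurrence is marked invalid and excluded from analysis).
    """

    trial_index: int
    phase: str
    stimulus_set: str
    identity: str
    position: int
    onset_s: float
    valid: bool

    @property
    def label(self) -> tuple[str, str, int, str]:
        return (self.stimulus_set, self.identity, self.position, self.phase)


@dataclass(frozen=True)
class CombinationScheme:
    """How same-label occurrences are merged into event regressors."""

    n_per_regressor: int = 3
    spacing_rule: str = "pseudo_random_spread"
    remainder_policy: str = "last_regressor_takes_remainder"

    def __post_init__(self):
        if self.n_per_regressor < 1:
            raise ValueError("n_per_regressor must be >= 1")


@dataclass(frozen=True)
class Regressor:
    label: tuple[str, str, int, str]
    occurrences: tuple[EventOccurrence, ...]

    @property
    def phase(self) -> str:
        return self.label[3]

    @property
    def position(self) -> int:
        return self.label[2]

    @property
    def onsets(self) -> tuple[float, ...]:
        return tuple(o.onset_s for o in self.occurrences)


@dataclass
class RegressorSet:
    regressors: list[Regressor]

    @property
    def counts_by_phase(self) -> dict[str, int]:
        return dict(Counter(r.phase for r in self.regressors))

    def __len__(self) -> int:
        return len(self.regressors)

    def labels_frame(self) -> pd.DataFrame:
        rows = [
            {
                "stimulus_set": r.label[0],
                "identity": r.label[1],
                "position": r.label[2],
                "phase": r.label[3],
                "n_occurrences": len(r.occurrences),
            }
            for r in self.regressors
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# design generation
# ---------------------------------------------------------------------------

def _largest_remainder(n: int, proportions: Mapping[int, float]) -> dict[int, int]:
    """Integer counts summing to ``n`` closest to the target proportions."""
    keys = sorted(proportions)
    raw = {k: n * proportions[k] for k in keys}
    counts = {k: int(math.floor(raw[k])) for k in keys}
    short = n - sum(counts.values())
    for k in sorted(keys, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def _balanced_order_choice(rng, length: int, position_counts) -> tuple[str, ...]:
    """Pick the permutation that keeps per-position identity counts most even."""
    best, best_cost = None, None
    perms = list(itertools.permutations(IDENTITIES, length))
    rng.shuffle(perms)
    for perm in perms:
        cost = 0.0
        for pos, ident in enumerate(perm, start=1):
            counts = position_counts[pos]
            cost += counts[ident] - min(counts.values(), default=0)
        if best_cost is None or cost < best_cost:
            best, best_cost = perm, cost
    return tuple(best)


def generate_design(
    seed: int,
    n_trials: int = 96,
    length_distribution: Mapping[int, float] = DEFAULT_LENGTH_DISTRIBUTION,
    probed_fraction: float = 2.0 / 3.0,
    n_changed_probes: int = 8,
    stimulus_sets: Sequence[str] = STIMULUS_SETS,
    item_duration_s: float = 3.5,
    post_sequence_delay_s: float = 2.0,
    rest_range_s: tuple[float, float] = (6.0, 16.0),
    tr_s: float = 1.75,
    lead_in_s: float = 10.5,
    tail_s: float = 21.0,
    balance_identities: bool = False,
) -> ExperimentDesign:
    """Generate a randomized run schedule.

    Sequence lengths, stimulus sets, item orders and probe flags are assigned
    pseudo-randomly (seed-determined); rest durations are uniform on
    ``rest_range_s``.  ``balance_identities=True`` greedily equates how often
    each identity appears at each position.
    """
    if n_trials < 0:
        raise ValueError("n_trials must be non-negative")
    if not 0.0 <= probed_fraction <= 1.0:
        raise ValueError("probed_fraction must lie in [0, 1]")
    if abs(sum(length_distribution.values()) - 1.0) > 1e-6:
        raise ValueError("length_distribution proportions must sum to 1")
    if any(k not in (1, 2, 3) for k in length_distribution):
        raise ValueError("sequence lengths must be 1, 2 or 3")

    rng = np.random.default_rng(seed)
    if n_trials == 0:
        return ExperimentDesign(trials=[], tr_s=tr_s, n_volumes=0)

    counts = _largest_remainder(n_trials, length_distribution)
    lengths = [k for k in sorted(counts) for _ in range(counts[k])]
    rng.shuffle(lengths)

    sets = [stimulus_sets[i % len(stimulus_sets)] for i in range(n_trials)]
    rng.shuffle(sets)

    n_probed = int(round(probed_fraction * n_trials))
    probed_idx = set(rng.choice(n_trials, size=n_probed, replace=False).tolist())
    changeable = [i for i in sorted(probed_idx) if lengths[i] >= 2]
    if n_changed_probes > len(changeable):
        raise ValueError(
            f"cannot place {n_changed_probes} changed probes: only "
            f"{len(changeable)} probed trials have length >= 2"
        )
    changed_idx = set(
        rng.choice(changeable, size=n_changed_probes, replace=False).tolist()
    ) if n_changed_probes else set()

    position_counts = {p: Counter() for p in (1, 2, 3)}
    trials: list[Trial] = []
    t = lead_in_s
    for i in range(n_trials):
        length = lengths[i]
        if balance_identities:
            order = _balanced_order_choice(rng, length, position_counts)
        else:
            order = tuple(rng.permutation(IDENTITIES)[:length])
        for pos, ident in enumerate(order, start=1):
            position_counts[pos][ident] += 1
        probe_order = order
        if i in changed_idx:
            alternatives = [p for p in itertools.permutations(order) if p != order]
            probe_order = alternatives[rng.integers(len(alternatives))]
        trial = Trial(
            index=i,
            stimulus_set=sets[i],
            length=length,
            item_order=order,
            has_recognition=i in probed_idx,
            probe_changed=i in changed_idx,
            probe_order=probe_order,
            onset_s=t,
            rest_s=float(rng.uniform(*rest_range_s)),
            item_duration_s=item_duration_s,
            post_sequence_delay_s=post_sequence_delay_s,
        )
        trials.append(trial)
        t = trial.end_s
    n_volumes = int(math.ceil((t + tail_s) / tr_s))
    design = ExperimentDesign(trials=trials, tr_s=tr_s, n_volumes=n_volumes)
    design.validate()
    return design


# ---------------------------------------------------------------------------
# the published per-set trial-structure preset
# ---------------------------------------------------------------------------

# One stimulus set's worth of the published session: 48 trials (8 one-item,
# 18 two-item, 22 three-item), of which 5/12/15 per length are probed.  Item
# orders are constructed so identities appear at each position as equally as
# possible, for presentation and for the probed (recognition) subset alike:
#   presentation  pos1 {16,16,16}  pos2 {14,13,13}  pos3 {8,7,7}
#   recognition   pos1 {11,11,10}  pos2 {9,9,9}     pos3 {5,5,5}
# Grouping each label's occurrences in threes then yields 42 presentation and
# 27 recognition regressors (69 in total).
_ALL_PERMS3 = list(itertools.permutations("ABC"))
_ALL_PAIRS = list(itertools.permutations("ABC", 2))

_PRESET_PROBED_LEN3 = _ALL_PERMS3 * 2 + [("A", "B", "C"), ("B", "C", "A"), ("C", "A", "B")]
_PRESET_PROBED_LEN2 = _ALL_PAIRS * 2
_PRESET_PROBED_LEN1 = [("A",), ("A",), ("B",), ("B",), ("C",)]
_PRESET_UNPROBED_LEN1 = [("A",), ("B",), ("C",)]
_PRESET_UNPROBED_LEN2 = [
    ("A", "B"), ("A", "C"), ("B", "A"), ("C", "A"), ("C", "A"), ("C", "B"),
]
_PRESET_UNPROBED_LEN3 = [
    ("B", "C", "A"), ("B", "C", "A"), ("B", "C", "A"),
    ("C", "A", "B"), ("C", "A", "B"),
    ("A", "B", "C"), ("A", "B", "C"),
]


def replicate_table_design(
    seed: int,
    stimulus_set: str = "houses",
    tr_s: float = 1.75,
    rest_range_s: tuple[float, float] = (6.0, 16.0),
    lead_in_s: float = 10.5,
    tail_s: float = 21.0,
) -> ExperimentDesign:
    """The published per-set trial structure with exact identity balance.

    Returns a 48-trial, single-stimulus-set schedule whose valid-occurrence
    counts reproduce the published regressor bookkeeping exactly (42
    presentation + 27 recognition regressors at n=3 per regressor).  Trial
    order, identity-role assignment and rest durations are seed-randomized;
    no changed probes are scheduled (the published counts describe the
    occurrences that survive the changed-probe exclusion rule).
    """
    rng = np.random.default_rng(seed)
    role_map = dict(zip("ABC", rng.permutation(list(IDENTITIES))))

    blueprint: list[tuple[tuple[str, ...], bool]] = []
    for order in _PRESET_PROBED_LEN1 + _PRESET_PROBED_LEN2 + _PRESET_PROBED_LEN3:
        blueprint.append((order, True))
    for order in _PRESET_UNPROBED_LEN1 + _PRESET_UNPROBED_LEN2 + _PRESET_UNPROBED_LEN3:
        blueprint.append((order, False))
    rng.shuffle(blueprint)

    trials: list[Trial] = []
    t = lead_in_s
    for i, (order, probed) in enumerate(blueprint):
        order = tuple(role_map[x] for x in order)
        trial = Trial(
            index=i,
            stimulus_set=stimulus_set,
            length=len(order),
            item_order=order,
            has_recognition=probed,
            probe_changed=False,
            probe_order=order,
            onset_s=t,
            rest_s=float(rng.uniform(*rest_range_s)),
        )
        trials.append(trial)
        t = trial.end_s
    n_volumes = int(math.ceil((t + tail_s) / tr_s))
    design = ExperimentDesign(trials=trials, tr_s=tr_s, n_volumes=n_volumes)
    design.validate()
    return design


# ---------------------------------------------------------------------------
# occurrences and regressor combination
# ---------------------------------------------------------------------------

def enumerate_occurrences(
    design: ExperimentDesign,
    incorrect_trials: Iterable[int] = (),
) -> list[EventOccurrence]:
    """One occurrence per displayed item per phase.

    Recognition occurrences exist only for probed trials.  An occurrence is
    invalid if its trial was answered incorrectly, or if it is a recognition
    item replayed at a position different from its presented one (changed
    probes).
    """
    incorrect = set(incorrect_trials)
    out: list[EventOccurrence] = []
    for trial in design.trials:
        trial_ok = trial.index not in incorrect
        for pos, (ident, onset) in enumerate(
            zip(trial.item_order, trial.presentation_onsets), start=1
        ):
            out.append(EventOccurrence(
                trial_index=trial.index, phase="presentation",
                stimulus_set=trial.stimulus_set, identity=ident,
                position=pos, onset_s=onset, valid=trial_ok,
            ))
        if trial.has_recognition:
            presented_pos = {ident: p for p, ident in enumerate(trial.item_order, 1)}
            for pos, (ident, onset) in enumerate(
                zip(trial.probe_order, trial.recognition_onsets), start=1
            ):
                out.append(EventOccurrence(
                    trial_index=trial.index, phase="recognition",
                    stimulus_set=trial.stimulus_set, identity=ident,
                    position=pos, onset_s=onset,
                    valid=trial_ok and presented_pos[ident] == pos,
                ))
    return out


def combine_occurrences(
    occurrences: Sequence[EventOccurrence],
    scheme: CombinationScheme = CombinationScheme(),
    seed: int = 0,
) -> RegressorSet:
    """Partition valid occurrences of each label into event regressors.

    Each label's occurrences form ``ceil(count / n)`` groups; all groups hold
    ``n`` members except the trailing ones, which absorb the remainder.  Group
    membership is assigned round-robin over the onset-ordered occurrences so a
    group's members are spread across the run; equal-onset ties are broken by a
    seeded shuffle.
    """
    rng = np.random.default_rng(seed)
    n = scheme.n_per_regressor
    by_label: dict[tuple, list[EventOccurrence]] = defaultdict(list)
    n_invalid = 0
    for occ in occurrences:
        if occ.valid:
            by_label[occ.label].append(occ)
        else:
            n_invalid += 1
    if n_invalid:
        logger.info("combine_occurrences: %d invalid occurrences excluded", n_invalid)

    regressors: list[Regressor] = []
    for label in sorted(by_label):
        occs = by_label[label]
        order = rng.permutation(len(occs))  # seeded tie-break for equal onsets
        occs = sorted((occs[i] for i in order), key=lambda o: o.onset_s)
        count = len(occs)
        k = math.ceil(count / n)
        capacity = [n] * k
        capacity[-1] = count - n * (k - 1)
        groups: list[list[EventOccurrence]] = [[] for _ in range(k)]
        g = 0
        for occ in occs:
            while len(groups[g % k]) >= capacity[g % k]:
                g += 1
            groups[g % k].append(occ)
            g += 1
        for members in groups:
            regressors.append(Regressor(label=label, occurrences=tuple(members)))
    empty_labels = [lbl for lbl in by_label if not by_label[lbl]]
    for lbl in empty_labels:
        logger.warning("label %s has no valid occurrences; no regressor emitted", lbl)
    return RegressorSet(regressors=regressors)


# ---------------------------------------------------------------------------
# behavioural summary & events-table output
# ---------------------------------------------------------------------------

def recognition_accuracy_percent(mean_incorrect: float, n_trials: int) -> float:
    """Mean recognition accuracy in percent from the mean error count."""
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    return 100.0 * (1.0 - mean_incorrect / n_trials)


def occurrences_to_events_table(occurrences: Sequence[EventOccurrence],
                                item_duration_s: float = 3.5) -> pd.DataFrame:
    """BIDS-events-style table: onset, duration, trial_type, valid."""
    rows = [
        {
            "onset": occ.onset_s,
            "duration": item_duration_s,
            "trial_type": f"{occ.stimulus_set}_{occ.identity}_pos{occ.position}_{occ.phase}",
            "valid": int(occ.valid),
        }
        for occ in sorted(occurrences, key=lambda o: o.onset_s)
    ]
    return pd.DataFrame(rows, columns=["onset", "duration", "trial_type", "valid"])


def events_table_to_occurrences(table: pd.DataFrame) -> list[EventOccurrence]:
    """Inverse of :func:`occurrences_to_events_table` (trial indices are lost)."""
    out = []
    for i, row in table.iterrows():
        sset, ident, pos, phase = row["trial_type"].split("_")
        out.append(EventOccurrence(
            trial_index=-1, phase=phase, stimulus_set=sset, identity=ident,
            position=int(pos.removeprefix("pos")), onset_s=float(row["onset"]),
            valid=bool(row["valid"]),
        ))
    return out
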