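"""Motion-state vocabulary for sit-to-stand / stand-to-sit (STS) cycles.

The motion is modelled as a cyclic automaton over four states::

    Sitting -> SiTSt -> Standing -> StTSi -> Sitting -> ...

where ``SiTSt`` is the sit-to-stand transition and ``StTSi`` the
stand-to-sit transition.  In the six-class vocabulary the two transition
states are additionally tagged with the movement strategy that produced
them: ``M-`` (momentum transfer) or ``S-`` (stabilization).  The two
static states are shared between strategies.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

SITTING = "Sitting"
SITST = "SiTSt"
STANDING = "Standing"
STTSI = "StTSi"

STATES_4 = (SITTING, SITST, STANDING, STTSI)

MOMENTUM = "momentum"
STABILIZATION = "stabilization"
STRATEGIES = (MOMENTUM, STABILIZATION)

#: strategy tag -> single-letter prefix used in the six-class labels
STRATEGY_PREFIX = {MOMENTUM: "M", STABILIZATION: "S"}

STATES_6 = (SITTING, "M-SiTSt", STANDING, "M-StTSi", "S-SiTSt", "S-StTSi")

#: next hold state after each transition state (4-class view)
_NEXT_HOLD = {SITST: STANDING, STTSI: SITTING}
#: transition state leaving each hold state (4-class view)
_NEXT_TRANSITION = {SITTING: SITST, STANDING: STTSI}


def collapse_to_four(labels: Sequence[str] | np.ndarray) -> np.ndarray:
    """Collapse six-class (strategy-tagged) labels to the four-class set."""
    arr = np.asarray(labels, dtype=object)
    out = np.empty(arr.shape, dtype=object)
    for i, lab in enumerate(arr.ravel()):
        out.ravel()[i] = lab.split("-", 1)[1] if "-" in lab else lab
    return out.astype(str)


def tag_strategy(label: str, strategy: str) -> str:
    """Map a 4-class label to its 6-class form under ``strategy``."""
    if label in (SITST, STTSI):
        return f"{STRATEGY_PREFIX[strategy]}-{label}"
    return label


def base_state(label: str) -> str:
    """Strip a strategy prefix, if any."""
    return label.split("-", 1)[1] if "-" in label else label


def is_transition(label: str) -> bool:
    return base_state(label) in (SITST, STTSI)


def legal_successors(label: str) -> set[str]:
    """States that may legally follow ``label`` (same vocabulary as input).

    Works for both the 4-class and the 6-class vocabulary.  From a hold
    state both strategy variants of the next transition are legal.
    """
    base = base_state(label)
    if base in _NEXT_HOLD:  # currently in a transition
        nxt = _NEXT_HOLD[base]
        return {label, nxt}
    nxt = _NEXT_TRANSITION[base]
    if "-" in label or label in (SITTING, STANDING):
        # 6-class: either strategy may initiate the transition
        return {label, f"M-{nxt}", f"S-{nxt}", nxt}
    return {label, nxt}


def is_valid_sequence(labels: Sequence[str]) -> bool:
    """True when every consecutive label pair obeys the cyclic automaton."""
    labels = list(labels)
    for a, b in zip(labels, labels[1:]):
        if b != a and b not in legal_successors(a):
            return False
    return True


def automaton_violations(labels: Sequence[str]) -> list[int]:
    """Indices ``i`` where ``labels[i] -> labels[i+1]`` is illegal."""
    labels = list(labels)
    return [
        i
        for i, (a, b) in enumerate(zip(labels, labels[1:]))
        if b != a and b not in legal_successors(a)
    ]
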