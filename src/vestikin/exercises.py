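"""The ten balance-stability exercises and their sensory-condition taxonomy.

Each exercise manipulates the proprioceptive condition (firm ground, unstable
surface, or tandem foot placement) and/or the visual condition (eyes open or
closed).  Exercises are grouped into three overlapping analysis categories —
tandem, eyes-closed, and unstable-surface — used by the comparison grids and
correlation maps; an exercise may belong to more than one category (tandem
stance with eyes closed is both a tandem and an eyes-closed exercise).
"""

from __future__ import annotations

from .exceptions import ValidationError

#: exercise id -> task name
EXERCISES: dict[int, str] = {
    1: "Tandem walk forward (FGA)",
    2: "Tandem walk forward",
    3: "Tandem walk backward",
    4: "Tandem stance eyes open",
    5: "Tandem stance eyes closed",
    6: "Standing on firm eyes closed",
    7: "Standing on foam eyes closed",
    8: "Standing on foam eyes open",
    9: "Foam cup balance 1 foot",
    10: "Foam cup alternatively foot",
}

#: exercise id -> proprioceptive condition
PROPRIOCEPTIVE: dict[int, str] = {
    1: "tandem", 2: "tandem", 3: "tandem", 4: "tandem", 5: "tandem",
    6: "firm",
    7: "unstable", 8: "unstable", 9: "unstable", 10: "unstable",
}

#: exercise id -> visual condition
VISUAL: dict[int, str] = {
    1: "open", 2: "open", 3: "open", 4: "open",
    5: "closed", 6: "closed", 7: "closed",
    8: "open", 9: "open", 10: "open",
}

CATEGORIES = ("tandem", "eyes_closed", "unstable_surface")

#: analysis category -> member exercise ids (sets overlap by design)
CATEGORY_MEMBERS: dict[str, frozenset[int]] = {
    "tandem": frozenset(e for e, p in PROPRIOCEPTIVE.items() if p == "tandem"),
    "eyes_closed": frozenset(e for e, v in VISUAL.items() if v == "closed"),
    "unstable_surface": frozenset(
        e for e, p in PROPRIOCEPTIVE.items() if p == "unstable"
    ),
}

#: named exercise subsets used for the composite kinematic score
SCORE_SUBSETS: dict[str, tuple[int, ...]] = {
    "foam-eyes-closed": (7,),
    "eyes-closed-2": (5, 7),
    "eyes-closed-3": (5, 6, 7),
}


def classify_exercise(exercise_id: int) -> frozenset[str]:
    """Return the set of analysis categories an exercise belongs to.

    Parameters
    ----------
    exercise_id
        Exercise id in 1..10.

    Returns
    -------
    frozenset of category names among ``{"tandem", "eyes_closed",
    "unstable_surface"}``; may contain more than one element.
    """
    if exercise_id not in EXERCISES:
        raise ValidationError(f"unknown exercise id: {exercise_id!r}")
    return frozenset(
        c for c, members in CATEGORY_MEMBERS.items() if exercise_id in members
    )
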