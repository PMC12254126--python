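"""Hierarchical cause-of-death classification.

The mortality outcome is coded as a tree: every death belongs to exactly one
leaf category, and counts are additive up the hierarchy (a "vascular" death is
also a "vascular-metabolic" death and an "all" death). Cause-specific hazard
analyses treat deaths from any other cause as censoring at the death age.
"""

from __future__ import annotations

# parent map: child -> parent; roots map to None
CAUSE_PARENT: dict[str, str | None] = {
    "all": None,
    "vascular-metabolic": "all",
    "non-vascular-metabolic": "all",
    "vascular": "vascular-metabolic",
    "renal": "vascular-metabolic",
    "hepatobiliary": "vascular-metabolic",
    "acute-diabetic-crisis": "vascular-metabolic",
    "cardiac": "vascular",
    "cerebrovascular": "vascular",
    "other-vascular": "vascular",
    "cancer": "non-vascular-metabolic",
    "respiratory": "non-vascular-metabolic",
    "infective": "non-vascular-metabolic",
    "external-other": "non-vascular-metabolic",
}

LEAF_CAUSES: tuple[str, ...] = tuple(
    c for c in CAUSE_PARENT if c not in set(CAUSE_PARENT.values())
)

#: default probability of each leaf cause conditional on death, proportional to
#: the cause-of-death mix of a large middle-aged urban Mexican cohort
#: (vascular deaths split 60/30/10 cardiac/cerebrovascular/other).
DEFAULT_CAUSE_MIX: dict[str, float] = {
    "cardiac": 3451 * 0.6 / 13066.0,
    "cerebrovascular": 3451 * 0.3 / 13066.0,
    "other-vascular": 3451 * 0.1 / 13066.0,
    "renal": 2034 / 13066.0,
    "hepatobiliary": 1069 / 13066.0,
    "acute-diabetic-crisis": 557 / 13066.0,
    "cancer": 2107 / 13066.0,
    "respiratory": 2050 / 13066.0,
    "infective": 811 / 13066.0,
    "external-other": 987 / 13066.0,
}


def validate_cause(cause: str) -> None:
    if cause not in CAUSE_PARENT:
        raise ValueError(
            f"unknown cause {cause!r}; known causes: {sorted(CAUSE_PARENT)}"
        )


def ancestors(cause: str) -> list[str]:
    """All causes on the path from ``cause`` up to the root, inclusive."""
    validate_cause(cause)
    out = [cause]
    while (p := CAUSE_PARENT[out[-1]]) is not None:
        out.append(p)
    return out


def descendants(cause: str) -> list[str]:
    """``cause`` plus everything below it in the tree."""
    validate_cause(cause)
    out = [cause]
    frontier = [cause]
    while frontier:
        nxt = [c for c, p in CAUSE_PARENT.items() if p in frontier]
        out.extend(nxt)
        frontier = nxt
    return out


def matches(leaf: str, target: str) -> bool:
    """True if a death with leaf label ``leaf`` counts as a ``target`` death."""
    return target in ancestors(leaf)
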