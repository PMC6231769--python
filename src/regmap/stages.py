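"""Canonical stage names for the two time courses.

The default schema uses 11 fixed time points: six wild-type developmental
stages followed by five ageing (glp-1) days.  Output-table column names are
derived from these identifiers, so they are defined once here.
"""

DEV_STAGES: tuple[str, ...] = (
    "wt_emb",
    "wt_l1",
    "wt_l2",
    "wt_l3",
    "wt_l4",
    "wt_ya",
)

AGEING_STAGES: tuple[str, ...] = (
    "glp1_d1",
    "glp1_d2",
    "glp1_d6",
    "glp1_d9",
    "glp1_d13",
)

STAGES: tuple[str, ...] = DEV_STAGES + AGEING_STAGES

COURSES: dict[str, tuple[str, ...]] = {
    "development": DEV_STAGES,
    "ageing": AGEING_STAGES,
}


def course_stages(course: str) -> tuple[str, ...]:
    """Stage names belonging to a named time course."""
    try:
        return COURSES[course]
    except KeyError:
        raise ValueError(
            f"unknown course {course!r}; expected one of {sorted(COURSES)}"
        ) from None
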