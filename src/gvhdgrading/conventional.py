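"""Rule-based overall aGVHD grading: MAGIC, Consensus (Keystone 1994),
IBMTR severity index and Minnesota.

Each system is a declarative rule table: a rule pairs an overall grade with
per-organ stage conditions (all conditions of one rule must hold for it to
trigger); the overall grade is the maximum over triggered rules, and
(0,0,0) is always grade 0.  IBMTR grades render as letters A-D but compare
as ordinals 1-4.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from gvhdgrading.cohort import CohortTable, OrganStages

ROMAN = {0: "0", 1: "I", 2: "II", 3: "III", 4: "IV", 5: "V", 6: "VI",
         7: "VII", 8: "VIII", 9: "IX", 10: "X", 11: "XI", 12: "XII"}
IBMTR_LETTERS = {0: "0", 1: "A", 2: "B", 3: "C", 4: "D"}

SYSTEMS = ("magic", "consensus", "ibmtr", "minnesota", "pc1", "hclust", "kmeans")

#: number of ordinal grades (excluding grade 0) per registered rule system
N_GRADES = 4


@dataclass(frozen=True)
class GradeAssignment:
    """One patient's overall grade under one grading system.

    ``grade`` is ordinal (0 = no aGVHD, 1..G); ``stage`` carries the finer
    PC1 stage where applicable.
    """

    system: str
    grade: int
    stage: Optional[int] = None

    def render(self) -> str:
        if self.system == "ibmtr":
            return IBMTR_LETTERS.get(self.grade, str(self.grade))
        return ROMAN.get(self.grade, str(self.grade))


@dataclass(frozen=True)
class Rule:
    """One row of a rule table: grade triggered when every stated organ
    condition (inclusive stage range) holds."""

    grade: int
    skin: Optional[tuple[int, int]] = None
    liver: Optional[tuple[int, int]] = None
    gi: Optional[tuple[int, int]] = None

    def triggered(self, stages: OrganStages) -> bool:
        for organ in ("skin", "liver", "gi"):
            bounds = getattr(self, organ)
            if bounds is not None:
                value = getattr(stages, organ)
                if not bounds[0] <= value <= bounds[1]:
                    return False
        return True


# Rule tables transcribed from the systems' defining publications.  Single-
# organ triggers are separate rules; conjunctive criteria (e.g. grade I =
# skin 1-2 with no liver/GI involvement) constrain all three organs.
RULE_TABLES: dict[str, tuple[Rule, ...]] = {
    "magic": (
        Rule(1, skin=(1, 2), liver=(0, 0), gi=(0, 0)),
        Rule(2, skin=(3, 3)),
        Rule(2, liver=(1, 1)),
        Rule(2, gi=(1, 1)),
        Rule(3, liver=(2, 3)),
        Rule(3, gi=(2, 3)),
        Rule(4, skin=(4, 4)),
        Rule(4, liver=(4, 4)),
        Rule(4, gi=(4, 4)),
    ),
    "consensus": (
        Rule(1, skin=(1, 2), liver=(0, 0), gi=(0, 0)),
        Rule(2, skin=(3, 3)),
        Rule(2, liver=(1, 1)),
        Rule(2, gi=(1, 1)),
        Rule(3, liver=(2, 3)),
        Rule(3, gi=(2, 4)),
        Rule(4, skin=(4, 4)),
        Rule(4, liver=(4, 4)),
    ),
    "ibmtr": (
        Rule(1, skin=(1, 1), liver=(0, 0), gi=(0, 0)),
        Rule(2, skin=(2, 2)),
        Rule(2, liver=(1, 2)),
        Rule(2, gi=(1, 2)),
        Rule(3, skin=(3, 3)),
        Rule(3, liver=(3, 3)),
        Rule(3, gi=(3, 3)),
        Rule(4, skin=(4, 4)),
        Rule(4, liver=(4, 4)),
        Rule(4, gi=(4, 4)),
    ),
    "minnesota": (
        Rule(1, skin=(1, 2), liver=(0, 0), gi=(0, 0)),
        Rule(2, skin=(3, 3)),
        Rule(2, liver=(1, 1)),
        Rule(2, gi=(1, 1)),
        Rule(3, liver=(2, 4)),
        Rule(3, gi=(2, 3)),
        Rule(4, skin=(4, 4)),
        Rule(4, gi=(4, 4)),
    ),
}


def _rule_grade(system: str, stages: OrganStages) -> GradeAssignment:
    if stages.is_zero:
        return GradeAssignment(system, 0)
    table = RULE_TABLES[system]
    triggered = [rule.grade for rule in table if rule.triggered(stages)]
    if not triggered:
        # cannot happen for the shipped tables (totality is tested
        # exhaustively), but a new variant table could be incomplete
        raise ValueError(
            f"{system} rule table assigns no grade to {stages.as_tuple()}"
        )
    return GradeAssignment(system, max(triggered))


def magic_grade(stages: OrganStages) -> GradeAssignment:
    """MAGIC overall grade (Mount Sinai aGVHD International Consortium)."""
    return _rule_grade("magic", stages)


def consensus_grade(stages: OrganStages) -> GradeAssignment:
    """Consensus (Keystone 1994) overall grade.

    Grade IV requires stage-4 skin or liver; stage-4 GI alone is grade III.
    """
    return _rule_grade("consensus", stages)


def ibmtr_index(stages: OrganStages) -> GradeAssignment:
    """IBMTR severity index A-D (stored as ordinals 1-4)."""
    return _rule_grade("ibmtr", stages)


def minnesota_grade(stages: OrganStages) -> GradeAssignment:
    """University of Minnesota overall grade.

    Liver stage 4 stays grade III; only stage-4 skin or GI triggers grade IV.
    """
    return _rule_grade("minnesota", stages)


RULE_GRADERS = {
    "magic": magic_grade,
    "consensus": consensus_grade,
    "ibmtr": ibmtr_index,
    "minnesota": minnesota_grade,
}


def grade_cohort(
    cohort: CohortTable, system: str, model=None, **kwargs
) -> list[GradeAssignment]:
    """Grade every patient of a cohort under one system, order preserved.

    Rule-based systems need no model; ``pc1``, ``hclust`` and ``kmeans``
    require their fitted model passed as ``model``.
    """
    if system in RULE_GRADERS:
        grader = RULE_GRADERS[system]
        return [
            grader(OrganStages(int(s), int(l), int(g)))
            for s, l, g in cohort.df[["skin", "liver", "gi"]].itertuples(index=False)
        ]
    if system == "pc1":
        from gvhdgrading import pc1 as _pc1

        if model is None:
            raise ValueError("system 'pc1' requires a fitted PC1Model")
        return _pc1.grade_cohort_pc1(cohort, model, **kwargs)
    if system in ("hclust", "kmeans"):
        from gvhdgrading import clustering as _clustering

        if model is None:
            raise ValueError(f"system {system!r} requires a fitted ClusterGradingModel")
        return _clustering.grade_cohort_clusters(cohort, model, **kwargs)
    raise ValueError(f"unknown grading system {system!r}; registered: {SYSTEMS}")
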