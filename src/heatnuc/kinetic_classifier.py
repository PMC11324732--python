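"""Rule-based classification of significance patterns into kinetic groups.

Each differentially accumulated protein carries a 6-tuple of signed
significance calls over the canonical contrasts C1..C6.  A decision
table maps patterns to one of six kinetic groups — Early (EG), Late
(LG), Transient (TG), Early Persistent (EPG), Late Persistent (LPG) and
Recovery (RG) — for a direction d in {+1, -1}; unmatched patterns stay
UNASSIGNED and are handed to profile clustering.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .differential import CONTRASTS

__all__ = [
    "GROUPS",
    "DecisionRule",
    "DEFAULT_RULES",
    "KineticAssignment",
    "build_pattern",
    "classify_pattern",
    "classify_all",
    "group_summary",
    "load_rules",
    "dump_rules",
    "rules_hash",
]

GROUPS = ("EG", "LG", "TG", "EPG", "LPG", "RG")

#: Constraint tokens, per contrast: the protein's direction "d", its
#: negation "-d", a required non-significant "0", or a wildcard "*".
_TOKENS = ("d", "-d", "0", "*")


@dataclass(frozen=True)
class DecisionRule:
    group: str
    constraints: tuple[str, ...]  # one token per contrast, C1..C6
    priority: int

    def __post_init__(self) -> None:
        if len(self.constraints) != len(CONTRASTS):
            raise ValueError("rule needs one constraint per contrast")
        for tok in self.constraints:
            if tok not in _TOKENS:
                raise ValueError(f"unknown constraint token {tok!r}")
        if self.constraints[0] == "*" or self.constraints[1] == "*":
            raise ValueError("every rule must constrain C1 and C2")

    def matches(self, pattern: tuple[int, ...], d: int) -> bool:
        for tok, call in zip(self.constraints, pattern):
            if tok == "d" and call != d:
                return False
            if tok == "-d" and call != -d:
                return False
            if tok == "0" and call != 0:
                return False
        return True


#: Default decision table transcribed from the group definitions; the
#: priority order is EG > LG > TG > EPG > LPG > RG, first match wins.
#: C5 is a wildcard throughout (never constrained by the definitions).
DEFAULT_RULES: tuple[DecisionRule, ...] = (
    DecisionRule("EG", ("d", "d", "0", "0", "*", "-d"), 1),
    DecisionRule("LG", ("0", "d", "0", "d", "*", "-d"), 2),
    DecisionRule("TG", ("d", "0", "0", "-d", "*", "*"), 3),
    DecisionRule("EPG", ("d", "d", "d", "0", "*", "0"), 4),
    DecisionRule("LPG", ("0", "d", "d", "d", "*", "0"), 5),
    DecisionRule("RG", ("0", "0", "d", "0", "*", "*"), 6),
)


@dataclass(frozen=True)
class KineticAssignment:
    accession: str
    group: str  # EG..RG or UNASSIGNED
    direction: int  # +1/-1, 0 for UNASSIGNED

    def __post_init__(self) -> None:
        if self.group != "UNASSIGNED" and self.direction == 0:
            raise ValueError("assigned group requires a nonzero direction")


def build_pattern(calls: pd.DataFrame | dict) -> tuple[int, ...]:
    """Order one protein's calls into the canonical C1..C6 tuple.

    Accepts a {contrast_id: call} mapping or a DataFrame with columns
    ``contrast`` and ``call``; each contrast must appear exactly once.
    """
    if isinstance(calls, pd.DataFrame):
        counts = calls["contrast"].value_counts()
        dup = counts[counts > 1]
        if not dup.empty:
            raise ValueError(f"duplicate calls for contrast(s): {list(dup.index)}")
        mapping = dict(zip(calls["contrast"], calls["call"]))
    else:
        mapping = dict(calls)
    pattern = []
    for c in CONTRASTS:
        if c.id not in mapping:
            raise ValueError(f"missing call for contrast {c.id}")
        v = int(mapping[c.id])
        if v not in (-1, 0, 1):
            raise ValueError(f"call must be in {{-1,0,1}}, got {v}")
        pattern.append(v)
    return tuple(pattern)


def classify_pattern(
    pattern: tuple[int, ...],
    rules: tuple[DecisionRule, ...] = DEFAULT_RULES,
    accession: str = "",
) -> KineticAssignment:
    """First-match classification over rules sorted by priority.

    For each rule (in priority order) direction +1 is tried before -1;
    a rule's d / -d / 0 tokens must all hold for the match to count.
    """
    for rule in sorted(rules, key=lambda r: r.priority):
        for d in (1, -1):
            if rule.matches(pattern, d):
                return KineticAssignment(accession, rule.group, d)
    return KineticAssignment(accession, "UNASSIGNED", 0)


def classify_all(
    ct: pd.DataFrame, rules: tuple[DecisionRule, ...] = DEFAULT_RULES
) -> pd.DataFrame:
    """Classify every DAP (>= 1 nonzero call) in a contrast table.

    Returns a DataFrame ``accession, group, direction`` sorted by
    accession; non-DAP proteins are excluded.
    """
    needed = {c.id for c in CONTRASTS}
    present = set(ct["contrast"].unique())
    if not needed.issubset(present):
        raise ValueError(f"contrast table missing contrasts: {sorted(needed - present)}")
    wide = ct.pivot(index="accession", columns="contrast", values="call")
    wide = wide[[c.id for c in CONTRASTS]]
    records = []
    for acc, row in wide.iterrows():
        pattern = tuple(int(v) for v in row)
        if all(v == 0 for v in pattern):
            continue  # not a DAP
        a = classify_pattern(pattern, rules, accession=str(acc))
        records.append({"accession": a.accession, "group": a.group, "direction": a.direction})
    out = pd.DataFrame(records, columns=["accession", "group", "direction"])
    return out.sort_values("accession", ignore_index=True)


def group_summary(assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-group counts split by direction (plus UNASSIGNED)."""
    rows = []
    for g in (*GROUPS, "UNASSIGNED"):
        sub = assignments[assignments["group"] == g]
        rows.append(
            {
                "group": g,
                "up": int((sub["direction"] == 1).sum()),
                "down": int((sub["direction"] == -1).sum()),
                "total": len(sub),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rules (de)serialization


def load_rules(path: str | Path) -> tuple[DecisionRule, ...]:
    """Load a YAML decision table: {group: {pattern: [tokens], priority: n}}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    rules = []
    for group, block in raw.items():
        rules.append(
            DecisionRule(
                group=str(group),
                constraints=tuple(str(t) for t in block["pattern"]),
                priority=int(block["priority"]),
            )
        )
    return tuple(sorted(rules, key=lambda r: r.priority))


def dump_rules(rules: tuple[DecisionRule, ...], path: str | Path) -> None:
    out = {
        r.group: {"pattern": list(r.constraints), "priority": r.priority}
        for r in rules
    }
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)


def rules_hash(rules: tuple[DecisionRule, ...] = DEFAULT_RULES) -> str:
    """Short content hash of a decision table (shown by ``--version``)."""
    payload = json.dumps(
        [[r.group, list(r.constraints), r.priority] for r in sorted(rules, key=lambda r: r.priority)]
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
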