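"""Bundled worked example: an 18-factor preschool drowning-risk system.

The package ships one fully worked risk-factor system — 18 common factors for
preschool-children drowning, classified by Haddon-matrix dimension (host,
medium, physical environment, social environment) — as published study tables
transcribed verbatim: the per-factor reachable/antecedent/intersection sets,
the five-level hierarchy, the per-dimension variance table from the
exploratory factor analysis, the reported global weights, and the survey
headcounts. Range notation such as ``"9–15"`` (hyphen or en-dash) is kept in
the raw strings and expanded on load; a checksum guards against accidental
edits.

Known internal inconsistencies of the bundled tables (kept verbatim, never
silently corrected):

* the hierarchy table lists 17 of the 18 factors — F8 appears in every other
  table but in no hierarchy row; the level-extraction rule places it in
  level 3;
* the printed antecedent set of F2 is {1, 2}, yet the printed reachable set
  of F16 contains 2, so the column read of the reconstructed reachability
  matrix gives Q(F2) = {1, 2, 16};
* the printed reachable sets are not transitively closed (e.g. R(F15) omits
  F4 and F5 although both are reachable through F13; R(F16) omits F3 although
  F2 is listed). :func:`ismanp.ism.check_closure` reports these violations.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from typing import Mapping

__all__ = ["StudyFixtures", "load_fixtures", "expand_range_list", "FACTOR_IDS"]

FACTOR_IDS = tuple(f"F{i}" for i in range(1, 19))

#: Per-factor (reachable set, antecedent set, intersection) — verbatim strings.
_REACHABILITY_ROWS: Mapping[int, tuple[str, str, str]] = {
    1: ("1–5", "1", "1"),
    2: ("2–5", "1, 2", "2"),
    3: ("3–5", "1–3", "3"),
    4: ("4", "1–4, 7–14, 16", "4"),
    5: ("5", "1–3, 5–14, 16", "5"),
    6: ("5, 6, 13", "6, 15, 16", "6"),
    7: ("4, 5, 7, 13", "7, 15, 16", "7"),
    8: ("4, 5, 8, 13", "8", "8"),
    9: ("4, 5, 9, 10, 13", "9, 15, 16", "9"),
    10: ("4, 5, 10, 13", "9, 10, 15, 16", "10"),
    11: ("4, 5, 11, 13", "11, 14–16", "11"),
    12: ("4, 5, 12, 13", "12, 15, 16", "12"),
    13: ("4, 5, 13", "6–16", "13"),
    14: ("4, 5, 11, 13, 14", "14–16", "14"),
    15: ("6, 7, 9–15, 17, 18", "15", "15"),
    16: ("2, 4–7, 9–14, 16–18", "16", "16"),
    17: ("17, 18", "15–17", "17"),
    18: ("18", "15–18", "18"),
}

#: Hierarchy level -> member factors, verbatim. Level 1 is the surface layer.
#: Note: F8 is absent from every row (see module docstring).
_HIERARCHY_ROWS: Mapping[int, str] = {
    1: "4, 5, 18",
    2: "3, 13, 17",
    3: "2, 6, 7, 10, 11, 12",
    4: "1, 9, 14",
    5: "15, 16",
}

#: Factor code -> (label, Haddon cluster).
_FACTOR_ROWS: Mapping[str, tuple[str, str]] = {
    "F1": ("Individual inherent characteristics", "host"),
    "F2": ("Physical and mental abilities and health status", "host"),
    "F3": ("Water skills and cognitive biases", "host"),
    "F4": ("Risky behaviors", "host"),
    "F5": ("Lack of immediate response and protection", "host"),
    "F6": ("Safety defects in equipment and facilities", "medium"),
    "F7": ("Risks related to vessels", "medium"),
    "F8": ("Characteristics of water environment", "medium"),
    "F9": ("Lack of protective facilities in places", "physical environment"),
    "F10": ("Environmental risks", "physical environment"),
    "F11": ("Family environmental exposure", "physical environment"),
    "F12": ("Supervision and time–space factors", "physical environment"),
    "F13": ("Caregiver behavior and supervision", "social environment"),
    "F14": ("Caregiver knowledge and cognition", "social environment"),
    "F15": ("Community safety and education system", "social environment"),
    "F16": ("Family economic background", "social environment"),
    "F17": ("Emergency preparedness and response mechanisms", "social environment"),
    "F18": ("Medical rescue and follow-up support", "social environment"),
}

CLUSTER_ORDER = ("host", "medium", "physical environment", "social environment")

#: Reported global weights and competition ranks (comparison only — the
#: expert judgment matrices behind them were never published).
_GLOBAL_WEIGHT_ROWS: Mapping[str, tuple[float, int]] = {
    "F4": (0.2806, 1),
    "F13": (0.2326, 2),
    "F5": (0.1469, 3),
    "F3": (0.0709, 4),
    "F2": (0.069, 5),
    "F14": (0.0405, 6),
    "F6": (0.0355, 7),
    "F18": (0.0329, 8),
    "F9": (0.0326, 9),
    "F11": (0.0231, 10),
    "F17": (0.014, 11),
    "F10": (0.0111, 12),
    "F12": (0.0072, 13),
    "F7": (0.0031, 14),
    "F1": (0.0, 15),
    "F8": (0.0, 15),
    "F15": (0.0, 15),
    "F16": (0.0, 15),
}

#: Per-dimension variance table: factor -> (dimension, eigenvalue,
#: variance contribution %, cumulative contribution %).
_VARIANCE_ROWS: Mapping[str, tuple[str, float, float, float]] = {
    "F1": ("host", 3.855, 35.047, 35.047),
    "F2": ("host", 2.105, 19.135, 54.182),
    "F3": ("host", 1.411, 12.826, 67.008),
    "F4": ("host", 1.274, 11.583, 78.591),
    "F5": ("host", 1.073, 9.758, 88.349),
    "F6": ("medium", 3.381, 42.256, 42.256),
    "F7": ("medium", 2.376, 29.695, 71.952),
    "F8": ("medium", 1.244, 15.556, 87.508),
    "F9": ("physical environment", 3.722, 41.355, 41.355),
    "F10": ("physical environment", 1.573, 17.48, 58.836),
    "F11": ("physical environment", 1.478, 16.424, 75.26),
    "F12": ("physical environment", 1.039, 11.55, 86.81),
    "F13": ("social environment", 4.569, 24.05, 24.05),
    "F14": ("social environment", 4.188, 22.04, 46.09),
    "F15": ("social environment", 2.323, 12.225, 58.315),
    "F16": ("social environment", 2.195, 11.552, 69.867),
    "F17": ("social environment", 2.039, 10.732, 80.599),
    "F18": ("social environment", 1.134, 5.966, 86.566),
}

#: Survey bookkeeping used by the printed-arithmetic checks.
_SURVEY_COUNTS: Mapping[str, int] = {
    "questionnaires_distributed": 220,
    "questionnaires_valid": 205,
    "male": 87,
    "female": 118,
    "researchers": 55,
    "pediatricians": 48,
    "emergency_rescue": 52,
    "kindergarten_workers": 50,
}

_CHECKSUM = "226fea19811818ee0a5777dbba93ab4127513e2d90df19d45d95ad7dca5d45cb"


def _canonical_payload() -> str:
    return json.dumps(
        {
            "reachability": {str(k): list(v) for k, v in _REACHABILITY_ROWS.items()},
            "hierarchy": {str(k): v for k, v in _HIERARCHY_ROWS.items()},
            "factors": {k: list(v) for k, v in _FACTOR_ROWS.items()},
            "weights": {k: list(v) for k, v in _GLOBAL_WEIGHT_ROWS.items()},
            "variance": {k: list(v) for k, v in _VARIANCE_ROWS.items()},
            "survey": dict(_SURVEY_COUNTS),
        },
        sort_keys=True,
        ensure_ascii=False,
    )


def expand_range_list(text: str, lo: int = 1, hi: int = 18) -> tuple[int, ...]:
    """Expand ``"2, 4–7, 9–14"`` (hyphen or en-dash) to an ascending int tuple.

    Raises ``ValueError`` on duplicates, out-of-bounds indices, or empty/
    reversed ranges.
    """
    out: list[int] = []
    for part in text.split(","):
        part = part.strip().replace("–", "-")
        if not part:
            raise ValueError(f"empty element in range list {text!r}")
        m = re.fullmatch(r"(\d+)(?:-(\d+))?", part)
        if m is None:
            raise ValueError(f"malformed element {part!r} in range list {text!r}")
        a = int(m.group(1))
        b = int(m.group(2)) if m.group(2) else a
        if b < a:
            raise ValueError(f"reversed range {part!r} in {text!r}")
        out.extend(range(a, b + 1))
    if len(set(out)) != len(out):
        raise ValueError(f"duplicate indices in range list {text!r}")
    if out and (min(out) < lo or max(out) > hi):
        raise ValueError(f"index outside [{lo}, {hi}] in range list {text!r}")
    return tuple(sorted(out))


def _fset(indices: tuple[int, ...]) -> frozenset[str]:
    return frozenset(f"F{i}" for i in indices)


@dataclass(frozen=True)
class StudyFixtures:
    """Expanded, immutable view of the bundled example tables."""

    reachable_sets: Mapping[str, frozenset[str]]
    antecedent_sets: Mapping[str, frozenset[str]]
    intersection_sets: Mapping[str, frozenset[str]]
    hierarchy_levels: tuple[frozenset[str], ...]
    factor_labels: Mapping[str, str]
    cluster_of: Mapping[str, str]
    cluster_order: tuple[str, ...]
    global_weights: Mapping[str, float]
    global_ranks: Mapping[str, int]
    variance_rows: Mapping[str, tuple[str, float, float, float]]
    survey_counts: Mapping[str, int]
    factor_ids: tuple[str, ...] = field(default=FACTOR_IDS)

    def host_variance_rows(self) -> dict[str, tuple[float, float, float]]:
        """Eigenvalue / contribution / cumulative rows of the host dimension."""
        return {
            f: (ev, vc, cc)
            for f, (dim, ev, vc, cc) in self.variance_rows.items()
            if dim == "host"
        }


def load_fixtures() -> StudyFixtures:
    """Load and expand the bundled tables, verifying the transcription checksum."""
    digest = hashlib.sha256(_canonical_payload().encode("utf-8")).hexdigest()
    if digest != _CHECKSUM:
        raise RuntimeError(
            "bundled fixture tables fail their checksum "
            f"(got {digest}); the transcription has been edited"
        )
    reachable = {
        f"F{i}": _fset(expand_range_list(r)) for i, (r, _, _) in _REACHABILITY_ROWS.items()
    }
    antecedent = {
        f"F{i}": _fset(expand_range_list(q)) for i, (_, q, _) in _REACHABILITY_ROWS.items()
    }
    intersection = {
        f"F{i}": _fset(expand_range_list(x)) for i, (_, _, x) in _REACHABILITY_ROWS.items()
    }
    levels = tuple(
        _fset(expand_range_list(_HIERARCHY_ROWS[lvl])) for lvl in sorted(_HIERARCHY_ROWS)
    )
    return StudyFixtures(
        reachable_sets=reachable,
        antecedent_sets=antecedent,
        intersection_sets=intersection,
        hierarchy_levels=levels,
        factor_labels={k: v[0] for k, v in _FACTOR_ROWS.items()},
        cluster_of={k: v[1] for k, v in _FACTOR_ROWS.items()},
        cluster_order=CLUSTER_ORDER,
        global_weights={k: v[0] for k, v in _GLOBAL_WEIGHT_ROWS.items()},
        global_ranks={k: v[1] for k, v in _GLOBAL_WEIGHT_ROWS.items()},
        variance_rows=dict(_VARIANCE_ROWS),
        survey_counts=dict(_SURVEY_COUNTS),
    )
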