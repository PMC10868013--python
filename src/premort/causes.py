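"""Three-level cause-of-death grouping from ICD-10 underlying-cause codes.

Level 1 is the ICD-10 chapter (e.g. I00-I99, circulatory diseases).
Level 2 is a configurable code-range subcategory (e.g. I20-I25, ischaemic
heart disease) retained only if it accounts for more than a death-count
threshold over the full study window.  Level 3 is a single three-character
diagnosis (e.g. I20) inside a retained level-2 range, gated by the same
threshold.  The default threshold of 1,000 deaths keeps every retained node
large enough for stable rate estimation.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CHAPTERS",
    "DEFAULT_CANDIDATES",
    "CauseNode",
    "CauseHierarchy",
    "CodeValidationError",
    "HierarchyConfigError",
    "parse_icd10",
    "normalize_codes",
    "chapter_of",
    "build_hierarchy",
    "tabulate_by_cause",
]

UNCLASSIFIED = "unclassified"
ALL_CAUSE = "ALL"

#: ICD-10 chapter boundaries (code ranges are inclusive, compared as
#: letter+2-digit strings, which order correctly under lexicographic sort).
CHAPTERS: list[tuple[str, str, str]] = [
    ("A00", "B99", "Certain infectious and parasitic diseases"),
    ("C00", "D48", "Neoplasms"),
    ("D50", "D89", "Diseases of the blood and immune mechanism"),
    ("E00", "E90", "Endocrine, nutritional and metabolic diseases"),
    ("F00", "F99", "Mental and behavioural disorders"),
    ("G00", "G99", "Diseases of the nervous system"),
    ("H00", "H59", "Diseases of the eye and adnexa"),
    ("H60", "H95", "Diseases of the ear and mastoid process"),
    ("I00", "I99", "Diseases of the circulatory system"),
    ("J00", "J99", "Diseases of the respiratory system"),
    ("K00", "K93", "Diseases of the digestive system"),
    ("L00", "L99", "Diseases of the skin and subcutaneous tissue"),
    ("M00", "M99", "Diseases of the musculoskeletal system"),
    ("N00", "N99", "Diseases of the genitourinary system"),
    ("O00", "O99", "Pregnancy, childbirth and the puerperium"),
    ("P00", "P96", "Certain conditions originating in the perinatal period"),
    ("Q00", "Q99", "Congenital malformations and chromosomal abnormalities"),
    ("R00", "R99", "Symptoms, signs and abnormal findings"),
    ("S00", "T98", "Injury, poisoning and other external causes"),
    ("V01", "Y98", "External causes of morbidity and mortality"),
]

#: Default candidate level-2 ranges: the major premature-mortality groupings
#: (ischaemic heart disease, lung cancer, ...) commonly reported in
#: deprivation-gradient studies.  Editable configuration, not a closed list.
DEFAULT_CANDIDATES: list[tuple[str, str, str]] = [
    ("I20", "I25", "Ischaemic heart disease"),
    ("I60", "I69", "Cerebrovascular disease (stroke)"),
    ("C33", "C34", "Lung cancer"),
    ("C15", "C26", "Neoplasm of digestive system"),
    ("C50", "C50", "Breast cancer"),
    ("C51", "C58", "Cancer of female genital organs"),
    ("C64", "C68", "Neoplasm of urinary system"),
    ("J40", "J47", "Chronic lung disease"),
    ("J09", "J18", "Influenza and pneumonia"),
    ("K70", "K76", "Chronic liver disease"),
    ("V01", "X59", "Accidents"),
    ("X60", "X84", "Intentional self-harm"),
]


class CodeValidationError(ValueError):
    """Raised when ICD-10 codes cannot be normalized; lists the offenders."""


class HierarchyConfigError(ValueError):
    """Raised for invalid candidate-range configuration (e.g. overlaps)."""


_CODE_RE = re.compile(r"^([A-Za-z])(\d{2})")


def parse_icd10(code: str) -> str:
    """Normalize an ICD-10 code to its upper-case 3-character category.

    Sub-category detail ("I21.9", "I219") is discarded.  Raises
    :class:`CodeValidationError` for anything not starting with a letter
    followed by two digits.
    """
    m = _CODE_RE.match(str(code).strip())
    if m is None:
        raise CodeValidationError(f"malformed ICD-10 code: {code!r}")
    return (m.group(1) + m.group(2)).upper()


def normalize_codes(codes: pd.Series) -> pd.Series:
    """Vectorized :func:`parse_icd10`; raises listing all offending records."""
    s = codes.astype(str).str.strip().str.upper()
    extracted = s.str.extract(r"^([A-Z]\d{2})", expand=False)
    bad = s[extracted.isna()]
    if len(bad):
        sample = bad.head(20)
        raise CodeValidationError(
            f"{len(bad)} malformed ICD-10 code(s); offending records "
            f"(index: code): {dict(sample)}"
        )
    return extracted


_CH_STARTS = np.array([c[0] for c in CHAPTERS])
_CH_ENDS = np.array([c[1] for c in CHAPTERS])


def chapter_of(codes: pd.Series) -> pd.Series:
    """Map normalized 3-character codes to a chapter range label.

    Codes outside every chapter (e.g. U-codes) map to ``"unclassified"``
    with a warning.
    """
    arr = codes.to_numpy(dtype=object).astype(str)
    idx = np.searchsorted(_CH_STARTS, arr, side="right") - 1
    idx = np.clip(idx, 0, len(CHAPTERS) - 1)
    ok = (arr >= _CH_STARTS[idx]) & (arr <= _CH_ENDS[idx])
    labels = np.array([f"{s}-{e}" for s, e, _ in CHAPTERS], dtype=object)
    out = np.where(ok, labels[idx], UNCLASSIFIED)
    n_bad = int((~ok).sum())
    if n_bad:
        warnings.warn(
            f"{n_bad} death(s) with codes outside the ICD-10 chapter table "
            "routed to the 'unclassified' bucket",
            stacklevel=2,
        )
    return pd.Series(out, index=codes.index, name="chapter")


@dataclass(frozen=True)
class CauseNode:
    level: int              # 1 = chapter, 2 = code-range subcategory, 3 = 3-digit diagnosis
    start: str
    end: str
    label: str
    deaths: int
    parent: str | None = None

    @property
    def node_id(self) -> str:
        return self.start if self.start == self.end else f"{self.start}-{self.end}"


@dataclass
class CauseHierarchy:
    """Death-count-gated three-level ICD-10 grouping."""

    nodes: list[CauseNode] = field(default_factory=list)
    threshold: int = 1000

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "level": n.level,
                    "node": n.node_id,
                    "start": n.start,
                    "end": n.end,
                    "label": n.label,
                    "deaths": n.deaths,
                    "parent": n.parent,
                }
                for n in self.nodes
            ]
        )

    def level_nodes(self, level: int) -> list[CauseNode]:
        return [n for n in self.nodes if n.level == level]

    def annotate(self, codes: pd.Series) -> pd.DataFrame:
        """Per-death node membership: columns chapter / level2 / level3.

        Every death lands in exactly one chapter (or unclassified), at most
        one level-2 node and at most one level-3 node.
        """
        out = pd.DataFrame(index=codes.index)
        out["chapter"] = chapter_of(codes)
        arr = codes.to_numpy(dtype=object).astype(str)
        l2 = np.full(len(arr), None, dtype=object)
        for n in self.level_nodes(2):
            mask = (arr >= n.start) & (arr <= n.end)
            l2[mask] = n.node_id
        out["level2"] = l2
        l3_ids = {n.node_id for n in self.level_nodes(3)}
        out["level3"] = [c if c in l3_ids else None for c in arr]
        return out


def _validate_candidates(candidates: list[tuple[str, str, str]]) -> None:
    ordered = sorted(candidates)
    for (s1, e1, l1), (s2, e2, l2) in zip(ordered, ordered[1:]):
        if s2 <= e1:
            raise HierarchyConfigError(
                f"overlapping candidate ranges: {s1}-{e1} ({l1}) and {s2}-{e2} ({l2})"
            )
    for s, e, lab in candidates:
        if e < s:
            raise HierarchyConfigError(f"inverted range {s}-{e} ({lab})")


def build_hierarchy(
    codes: pd.Series,
    candidates: list[tuple[str, str, str]] | None = None,
    threshold: int = 1000,
) -> CauseHierarchy:
    """Build the gated hierarchy from normalized 3-character codes.

    A candidate range becomes a level-2 node iff it accounts for strictly
    more than ``threshold`` deaths pooled over all records supplied (both
    sexes, all deprivation levels, full study window); 3-digit diagnoses
    inside retained ranges are gated the same way.  Chapters need only one
    death.
    """
    if candidates is None:
        candidates = DEFAULT_CANDIDATES
    _validate_candidates(candidates)

    counts = normalize_codes(codes).value_counts()
    arr = counts.index.to_numpy(dtype=object).astype(str)
    n = counts.to_numpy()

    nodes: list[CauseNode] = []
    # level 1: chapters with at least one classified death
    for s, e, lab in CHAPTERS:
        total = int(n[(arr >= s) & (arr <= e)].sum())
        if total >= 1:
            nodes.append(CauseNode(1, s, e, lab, total))

    def _chapter_id(code: str) -> str | None:
        for s, e, _ in CHAPTERS:
            if s <= code <= e:
                return s if s == e else f"{s}-{e}"
        return None

    for s, e, lab in sorted(candidates):
        total = int(n[(arr >= s) & (arr <= e)].sum())
        if total > threshold:
            parent = _chapter_id(s)
            if parent is None or parent != _chapter_id(e):
                raise HierarchyConfigError(
                    f"candidate range {s}-{e} does not nest in a single chapter"
                )
            l2 = CauseNode(2, s, e, lab, total, parent=parent)
            nodes.append(l2)
            if s == e:
                # a single-code subcategory is its own diagnosis; a level-3
                # child would duplicate it
                continue
            in_range = (arr >= s) & (arr <= e)
            for code, cnt in sorted(zip(arr[in_range], n[in_range])):
                if cnt > threshold:
                    nodes.append(CauseNode(3, code, code, code, int(cnt), parent=l2.node_id))
    return CauseHierarchy(nodes=nodes, threshold=threshold)


def tabulate_by_cause(codes: pd.Series, hierarchy: CauseHierarchy) -> pd.DataFrame:
    """Recount deaths per hierarchy node for an arbitrary set of records."""
    norm = normalize_codes(codes)
    arr = norm.to_numpy(dtype=object).astype(str)
    rows = []
    for node in hierarchy.nodes:
        cnt = int(((arr >= node.start) & (arr <= node.end)).sum())
        rows.append({"level": node.level, "node": node.node_id, "label": node.label, "deaths": cnt})
    return pd.DataFrame(rows)
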