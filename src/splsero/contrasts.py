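"""Contrast definitions: which two sample subsets each comparison opposes.

The standard vocabulary covers the nine subgroup discriminations of the
study design (disease vs healthy, disease vs disease, Montreal-location
strata of Crohn's disease, and remission-restricted variants) plus the
univariate-only location contrasts.  Group A is listed first; fold changes
are reported as A relative to B.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["Contrast", "STANDARD_CONTRASTS", "get_contrast", "contrast_samples"]


@dataclass(frozen=True)
class Contrast:
    name: str
    label_a: str
    label_b: str
    filter_a: dict = field(default_factory=dict)
    filter_b: dict = field(default_factory=dict)

    def select(self, annot: pd.DataFrame, which: str) -> pd.Index:
        flt = self.filter_a if which == "a" else self.filter_b
        mask = pd.Series(True, index=annot.index)
        for col, allowed in flt.items():
            allowed = [allowed] if isinstance(allowed, str) else list(allowed)
            mask &= annot[col].isin(allowed)
        return annot.index[mask]


def _c(name, label_a, label_b, fa, fb) -> Contrast:
    return Contrast(name, label_a, label_b, fa, fb)


STANDARD_CONTRASTS: dict[str, Contrast] = {
    c.name: c
    for c in [
        _c("CD_vs_HC", "CD", "HC", {"group": "CD"}, {"group": "HC"}),
        _c("UC_vs_HC", "UC", "HC", {"group": "UC"}, {"group": "HC"}),
        _c("UC_vs_CD", "UC", "CD", {"group": "UC"}, {"group": "CD"}),
        _c("CD_vs_UC", "CD", "UC", {"group": "CD"}, {"group": "UC"}),
        _c(
            "L2CD_vs_L1L3CD",
            "L2CD",
            "L1L3CD",
            {"group": "CD", "location": ["L2"]},
            {"group": "CD", "location": ["L1", "L3"]},
        ),
        _c(
            "UC_vs_L1L3CD",
            "UC",
            "L1L3CD",
            {"group": "UC"},
            {"group": "CD", "location": ["L1", "L3"]},
        ),
        _c(
            "L1L3CD_vs_UC",
            "L1L3CD",
            "UC",
            {"group": "CD", "location": ["L1", "L3"]},
            {"group": "UC"},
        ),
        _c(
            "UC_vs_L2CD",
            "UC",
            "L2CD",
            {"group": "UC"},
            {"group": "CD", "location": ["L2"]},
        ),
        _c(
            "L2CD_vs_UC",
            "L2CD",
            "UC",
            {"group": "CD", "location": ["L2"]},
            {"group": "UC"},
        ),
        _c(
            "CDrem_vs_HC",
            "CDrem",
            "HC",
            {"group": "CD", "activity": ["remission"]},
            {"group": "HC"},
        ),
        _c(
            "UCrem_vs_HC",
            "UCrem",
            "HC",
            {"group": "UC", "activity": ["remission"]},
            {"group": "HC"},
        ),
        _c(
            "CDrem_vs_UCrem",
            "CDrem",
            "UCrem",
            {"group": "CD", "activity": ["remission"]},
            {"group": "UC", "activity": ["remission"]},
        ),
    ]
}

#: the nine discrimination tasks evaluated by double cross-validation
CV_CONTRASTS = (
    "CD_vs_HC",
    "UC_vs_HC",
    "UC_vs_CD",
    "L2CD_vs_L1L3CD",
    "UC_vs_L1L3CD",
    "UC_vs_L2CD",
    "CDrem_vs_HC",
    "UCrem_vs_HC",
    "CDrem_vs_UCrem",
)


def get_contrast(name: str) -> Contrast:
    try:
        return STANDARD_CONTRASTS[name]
    except KeyError:
        raise KeyError(
            f"unknown contrast {name!r}; known: {sorted(STANDARD_CONTRASTS)}"
        ) from None


def contrast_samples(annot: pd.DataFrame, contrast: Contrast | str) -> tuple[pd.Index, pd.Index]:
    """Resolve a contrast to its two disjoint sample-id sets."""
    if isinstance(contrast, str):
        contrast = get_contrast(contrast)
    ids_a = contrast.select(annot, "a")
    ids_b = contrast.select(annot, "b")
    overlap = ids_a.intersection(ids_b)
    if len(overlap):
        raise ValueError(f"contrast {contrast.name}: groups overlap ({list(overlap)[:5]})")
    if len(ids_a) == 0 or len(ids_b) == 0:
        raise ValueError(f"contrast {contrast.name}: empty group")
    return ids_a, ids_b
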