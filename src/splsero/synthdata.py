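"""Synthetic Olink-like serum proteomics cohorts with known ground truth.

Emulates a two-cohort inflammation-panel study of Crohn's disease (CD),
ulcerative colitis (UC) and healthy controls (HC): log2-scale protein
quantities built from per-protein baselines, a low-rank latent
"inflammation factor" term inducing inter-protein correlation, additive
group mean shifts of realistic magnitude (default |log2 FC| between about
0.26 and 1.25), Gaussian measurement noise, and per-protein LOD censoring —
including a handful of proteins censored in ~90% of samples, mimicking
assays that fail in serum.  Clinical strata (Montreal location of CD,
remission/active status, prior resection) follow the default cohort mix.

The generator is deterministic given (config, seed): structural parameters
(baselines, factor loadings, group shifts) are shared between the discovery
and replication cohorts, while sample-level noise is cohort-specific, so
the replication behaves like an independent re-measurement of the same
panel.  Censored cells keep their true value in ``NPXMatrix.values`` (the
mask alone marks censoring) until preprocessing resets them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contrasts import get_contrast
from .data_io import NPXMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "default_de_spec",
    "generate_cohort",
    "generate_study",
    "write_cohort_tsv",
]

# Named panel proteins carrying the default differential effects, with the
# default linear fold changes (group relative to HC unless stated).
_CD_EFFECTS = (
    ("FGF-19", "O95750", 0.42),
    ("MIP-1 alpha", "P10147", 0.58),
    ("TGF-alpha", "P01135", 0.68),
    ("TNFSF14", "O43557", 0.80),
    ("SCF", "P21583", 0.82),
    ("MMP-10", "P09238", 1.22),
    ("FGF-23", "Q9GZV9", 1.22),
    ("CCL11", "P51671", 1.23),
    ("IFN-gamma", "P01579", 1.23),
    ("IL-18", "Q14116", 1.25),
    ("IL-17A", "Q16552", 1.25),
    ("EN-RAGE", "P80511", 1.31),
    ("IL-10RA", "Q13651", 1.32),
    ("CXCL11", "O14625", 1.34),
    ("CASP-8", "Q14790", 1.36),
    ("CXCL9", "Q07325", 1.41),
    ("IL-6", "P05231", 1.42),
)
_UC_EFFECTS = (
    ("MIP-1 alpha", "P10147", 0.56),
    ("TGF-alpha", "P01135", 0.70),
    ("CCL20", "P78556", 0.70),
    ("OSM", "P13725", 0.77),
    ("TNFSF14", "O43557", 0.78),
    ("TRANCE", "O14788", 0.81),
    ("SCF", "P21583", 0.82),
    ("CASP-8", "Q14790", 1.21),
    ("CXCL9", "Q07325", 1.25),
    ("MMP-10", "P09238", 1.29),
    ("EN-RAGE", "P80511", 1.37),
    ("IL-5", "P05113", 1.50),
    # weak UC shift of FGF-19 so that CD vs UC lands at ~0.51 while staying
    # sub-threshold-ish for UC vs HC (0.42 / 0.51)
    ("FGF-19", "O95750", 0.42 / 0.51),
)
# assays that fail in serum: censored in ~90% of samples
_HIGH_LOD = (
    ("IL-13", "P35225"),
    ("IL-33", "O95760"),
    ("IL-1 alpha", "P01583"),
    ("TSLP", "Q969D9"),
)

_UNIPROT = {sym: acc for sym, acc, _ in _CD_EFFECTS + _UC_EFFECTS}
_UNIPROT.update(dict(_HIGH_LOD))


def default_de_spec() -> tuple[tuple[str, str, float], ...]:
    """Default differential effects: (protein symbol, contrast, log2 effect)."""
    spec = [(sym, "CD_vs_HC", float(np.log2(fc))) for sym, _, fc in _CD_EFFECTS]
    spec += [(sym, "UC_vs_HC", float(np.log2(fc))) for sym, _, fc in _UC_EFFECTS]
    return tuple(spec)


def _panel_symbols(n_proteins: int) -> list[str]:
    named = [sym for sym, _, _ in _CD_EFFECTS]
    named += [sym for sym, _, _ in _UC_EFFECTS if sym not in named]
    named += [sym for sym, _ in _HIGH_LOD]
    if n_proteins <= len(named):
        return named[:n_proteins]
    return named + [f"PROT{i:02d}" for i in range(len(named) + 1, n_proteins + 1)]


# Cohort composition (fractions of the group size); the defaults reproduce
# the study's clinical mix exactly at the default group sizes.
_STRATA = {
    "discovery": {
        "cd_location": np.array([15, 13, 22, 4]) / 54,   # L1, L2, L3, L4
        "cd_activity": np.array([37, 16, 1]) / 54,       # remission, active, unknown
        "uc_activity": np.array([42, 12, 0]) / 54,
        "cd_resection": 35 / 54,
        "uc_resection": 6 / 54,
    },
    "replication": {
        "cd_location": np.array([6, 14, 10, 0]) / 30,
        "cd_activity": np.array([24, 6, 0]) / 30,
        "uc_activity": np.array([22, 8, 0]) / 30,
        "cd_resection": 16 / 30,
        "uc_resection": 3 / 30,
    },
}
# share of resected CD patients having ileal involvement (L1/L3)
_ILEAL_RESECTION_SHARE = 0.8


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic two-cohort design."""

    n_discovery: tuple[int, int, int] = (54, 54, 54)     # CD, UC, HC
    n_replication: tuple[int, int, int] = (30, 30, 30)
    n_proteins: int = 91
    de_spec: tuple = field(default_factory=default_de_spec)
    sd: float = 0.5                    # within-group log2 noise sd
    n_factors: int = 2                 # latent inflammation factors
    factor_loading_sd: float = 0.3     # loading scale of the latent factors
    lod_quantile: float = 0.02         # default per-protein censoring quantile
    high_lod_quantile: float = 0.9     # for the designated failing assays
    high_lod_proteins: tuple = tuple(sym for sym, _ in _HIGH_LOD)
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.lod_quantile, self.high_lod_quantile):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("LOD quantiles must lie in [0, 1]")
        if not np.isfinite([e for _, _, e in self.de_spec]).all():
            raise ValueError("effects must be finite")


@dataclass
class GroundTruth:
    """Injected effects and censoring, for oracle tests."""

    protein_ids: list[str]
    group_shifts: dict  # group -> np.ndarray of log2 shifts (HC all-zero)
    lod: np.ndarray     # per-protein LOD used for this cohort
    de_spec: tuple

    def ground_truth(self, contrast: str) -> list[tuple[str, float]]:
        """True signed log2 effects for a contrast (group A minus group B).

        Strata of a disease group (location, activity) inherit the group
        shift; unknown contrasts raise.
        """
        con = get_contrast(contrast)
        ga = con.filter_a.get("group")
        gb = con.filter_b.get("group")
        if ga is None or gb is None:
            raise KeyError(f"contrast {contrast!r} does not resolve to groups")
        diff = self.group_shifts[ga] - self.group_shifts[gb]
        return [
            (pid, float(d)) for pid, d in zip(self.protein_ids, diff) if d != 0.0
        ]


def _allocate(fracs: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder allocation of ``n`` samples to strata fractions."""
    raw = fracs * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="mergesort")
    counts[order[:rem]] += 1
    return counts


def _group_shifts(config: SimulationConfig, symbols: list[str]) -> dict:
    index = {s: i for i, s in enumerate(symbols)}
    shifts = {g: np.zeros(config.n_proteins) for g in ("CD", "UC", "HC")}
    for ref, contrast, effect in config.de_spec:
        pid = symbols[ref] if isinstance(ref, (int, np.integer)) else ref
        if pid not in index:
            raise ValueError(f"de_spec references unknown protein {ref!r}")
        con = get_contrast(contrast)
        ga = con.filter_a.get("group")
        gb = con.filter_b.get("group")
        if ga is None or gb is None or gb != "HC":
            raise ValueError(
                f"de_spec contrast {contrast!r} must be a group-vs-HC contrast"
            )
        shifts[ga][index[pid]] += effect
    return shifts


def generate_cohort(
    config: SimulationConfig, cohort: str = "discovery"
) -> tuple[NPXMatrix, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate one cohort: (NPXMatrix, protein_meta, annotations, truth)."""
    if cohort not in ("discovery", "replication"):
        raise ValueError("cohort must be 'discovery' or 'replication'")
    p = config.n_proteins
    symbols = _panel_symbols(p)
    shifts = _group_shifts(config, symbols)

    rng_struct = np.random.default_rng([config.seed, 0])
    baseline = rng_struct.uniform(0.0, 10.0, size=p)
    loadings = rng_struct.normal(0.0, config.factor_loading_sd, size=(config.n_factors, p))

    rng = np.random.default_rng([config.seed, 1 if cohort == "discovery" else 2])
    sizes = dict(zip(("CD", "UC", "HC"), config.n_discovery if cohort == "discovery" else config.n_replication))
    prefix = "D" if cohort == "discovery" else "R"

    rows, sample_ids, groups = [], [], []
    for g in ("CD", "UC", "HC"):
        n_g = sizes[g]
        factors = rng.standard_normal((n_g, config.n_factors))
        noise = rng.normal(0.0, config.sd, size=(n_g, p))
        block = baseline + shifts[g] + factors @ loadings + noise
        rows.append(block)
        sample_ids += [f"{prefix}-{g}-{i + 1:03d}" for i in range(n_g)]
        groups += [g] * n_g
    values = np.vstack(rows)

    quantiles = np.full(p, config.lod_quantile)
    for sym in config.high_lod_proteins:
        if sym in symbols:
            quantiles[symbols.index(sym)] = config.high_lod_quantile
    lod = np.array([np.quantile(values[:, j], quantiles[j]) for j in range(p)])
    below = values < lod

    matrix = NPXMatrix(
        pd.DataFrame(values, index=pd.Index(sample_ids, name="sample_id"), columns=symbols),
        pd.DataFrame(below, index=pd.Index(sample_ids, name="sample_id"), columns=symbols),
    )
    meta = pd.DataFrame(
        {
            "symbol": symbols,
            "uniprot": [_UNIPROT.get(s, "") for s in symbols],
            "lod": lod,
        },
        index=pd.Index(symbols, name="protein_id"),
    )
    annot = _annotate(sample_ids, groups, cohort, sizes, rng)
    truth = GroundTruth(
        protein_ids=symbols, group_shifts=shifts, lod=lod, de_spec=config.de_spec
    )
    return matrix, meta, annot, truth


def _annotate(sample_ids, groups, cohort, sizes, rng) -> pd.DataFrame:
    strata = _STRATA[cohort]
    annot = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cohort": cohort,
            "group": groups,
            "location": "none",
            "activity": "unknown",
            "prior_resection": "unknown",
        }
    ).set_index("sample_id", drop=False)

    # CD: Montreal location, activity, resection (resection enriched in L1/L3)
    cd_ids = annot.index[annot["group"] == "CD"].to_numpy()
    loc_counts = _allocate(strata["cd_location"], sizes["CD"])
    locations = np.repeat(["L1", "L2", "L3", "L4"], loc_counts)
    rng.shuffle(locations)
    annot.loc[cd_ids, "location"] = locations

    act_counts = _allocate(strata["cd_activity"], sizes["CD"])
    activities = np.repeat(["remission", "active", "unknown"], act_counts)
    rng.shuffle(activities)
    annot.loc[cd_ids, "activity"] = activities

    n_res = int(round(strata["cd_resection"] * sizes["CD"]))
    ileal = cd_ids[np.isin(annot.loc[cd_ids, "location"], ["L1", "L3"])]
    other = cd_ids[~np.isin(annot.loc[cd_ids, "location"], ["L1", "L3"])]
    n_ileal_res = min(len(ileal), int(round(_ILEAL_RESECTION_SHARE * n_res)))
    n_other_res = min(len(other), n_res - n_ileal_res)
    annot.loc[cd_ids, "prior_resection"] = "no"
    annot.loc[rng.permutation(ileal)[:n_ileal_res], "prior_resection"] = "yes"
    annot.loc[rng.permutation(other)[:n_other_res], "prior_resection"] = "yes"

    # UC: activity and resection only
    uc_ids = annot.index[annot["group"] == "UC"].to_numpy()
    act_counts = _allocate(strata["uc_activity"], sizes["UC"])
    activities = np.repeat(["remission", "active", "unknown"], act_counts)
    rng.shuffle(activities)
    annot.loc[uc_ids, "activity"] = activities
    n_res = int(round(strata["uc_resection"] * sizes["UC"]))
    annot.loc[uc_ids, "prior_resection"] = "no"
    annot.loc[rng.permutation(uc_ids)[:n_res], "prior_resection"] = "yes"
    return annot


def generate_study(config: SimulationConfig) -> dict:
    """Generate both cohorts; returns a dict keyed by cohort name."""
    out = {}
    for cohort in ("discovery", "replication"):
        matrix, meta, annot, truth = generate_cohort(config, cohort)
        out[cohort] = {
            "matrix": matrix,
            "protein_meta": meta,
            "annotations": annot,
            "truth": truth,
        }
    return out


def write_cohort_tsv(matrix: NPXMatrix, meta: pd.DataFrame, annot: pd.DataFrame, outdir, cohort: str) -> dict:
    """Write a cohort in the TSV dialect that :mod:`splsero.data_io` reads.

    The NPX file embeds the LOD row; annotations go in a sidecar table.
    Returns the written paths.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    npx_path = outdir / f"{cohort}_npx.tsv"
    with_lod = matrix.values.copy()
    with_lod.loc["LOD"] = meta["lod"].to_numpy()
    with_lod.to_csv(npx_path, sep="\t", index_label="sample_id", float_format="%.17g")
    annot_path = outdir / f"{cohort}_annotations.tsv"
    annot.to_csv(annot_path, sep="\t", index=False)
    meta_path = outdir / f"{cohort}_proteins.tsv"
    meta.to_csv(meta_path, sep="\t", index_label="protein_id", float_format="%.17g")
    return {"npx": npx_path, "annotations": annot_path, "proteins": meta_path}
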