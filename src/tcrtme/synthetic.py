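"""Synthetic cohort generator with planted ground truth.

Every downstream stage of the package (repertoire QC, clonal dynamics, expression
signatures, TME subtyping, neoantigen linkage, clinical statistics) is exercised on
data from this module, so each generator plants a known truth that the analysis is
expected to recover:

* clone frequencies follow a truncated power law (rank-frequency ``p_i ~ i^-a``)
  and observed counts are multinomial draws at a configured template depth;
* paired pre/post tumour repertoires share a configured fraction of clonotypes
  (the intratumoral T cell clones, ITCs); a planted subset of those is expanded by
  a known factor, a subset contracted, and the remainder held exactly at its
  pre-treatment probability (the contracted set absorbs the renormalisation mass,
  so stable clones are an exact null for the expansion test);
* longitudinal blood samples seed a subset of ITC clones with per-timepoint scale
  factors on top of a power-law background;
* the expression matrix carries group shifts on designated IFN/EMT genes and
  hallmark-coherent shifts defining three TME subtypes;
* the clinical table has residual-tumour percentages tied to responder labels and
  exponential survival times with a stage confounder that is imbalanced across the
  two treatment arms (null arm effect by default, so IPTW should restore balance);
* neoantigen affinities and TCR-pair percentile ranks carry a configured
  true-binder enrichment.

All randomness flows from a single master seed split into named per-component
streams, so identical configuration + seed reproduces every table byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .repertoire import ClonotypeTable, write_clonotype_table

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
V_GENES = [f"TRBV{i}" for i in range(1, 33)]  # 32 V primers
J_GENES = [f"TRBJ{i}" for i in range(1, 14)]  # 13 J primers
D_GENES = ["TRBD1", "TRBD2", "."]

#: the 13 hallmark gene sets used for TME subtyping, grouped by the subtype they mark
HALLMARK_GROUPS: Mapping[str, list[str]] = {
    "IE": [
        "HALLMARK_INTERFERON_GAMMA_RESPONSE",
        "HALLMARK_INTERFERON_ALPHA_RESPONSE",
        "HALLMARK_INFLAMMATORY_RESPONSE",
    ],
    "tumor_proliferation": [
        "HALLMARK_E2F_TARGETS",
        "HALLMARK_MYC_TARGETS_V1",
        "HALLMARK_DNA_REPAIR",
        "HALLMARK_MTORC1_SIGNALING",
    ],
    "fibroblast_enriched": [
        "HALLMARK_EPITHELIAL_MESENCHYMAL_TRANSITION",
        "HALLMARK_TGF_BETA_SIGNALING",
        "HALLMARK_KRAS_SIGNALING_UP",
        "HALLMARK_ANGIOGENESIS",
    ],
}
EXTRA_HALLMARKS = ["HALLMARK_APOPTOSIS", "HALLMARK_GLYCOLYSIS"]
ALL_HALLMARKS = [h for group in HALLMARK_GROUPS.values() for h in group] + EXTRA_HALLMARKS

SUBTYPES = tuple(HALLMARK_GROUPS)  # ("IE", "tumor_proliferation", "fibroblast_enriched")

#: marker genes consumed by the formula-defined scores (kept in every expression matrix)
MARKER_GENES = [
    "CD2", "CD3D", "CD3E", "CD8A", "CD8B",
    "CD274", "HAVCR2", "TNFRSF9", "CTLA4", "TOX",
    "GZMB", "CXCL9", "CXCL10", "CCL5",
    "HLA-DRA", "HLA-DRB1", "HLA-DRB2", "HLA-DRB3", "HLA-DRB4", "HLA-DRB5",
    "HLA-DQA1", "HLA-DQA2", "HLA-DQB1", "HLA-DQB2", "HLA-DPA1", "HLA-DPB1",
    "FLT3", "CLEC9A", "XCR1", "GZMA", "PRF1", "IFNG", "CIITA",
]

STAGES = ("II", "III", "IV")
SITES = ("proximal", "middle", "distal")


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Deterministic per-component random stream derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(stream.encode())]))


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Cohort composition mirrors the trial (25 evaluable patients, 11 well / 14 poor
    responders).  Repertoire depth and clone number are not reported per sample and
    default to 100,000 templates over 1,000 clonotypes; both are configurable.
    """

    n_patients: int = 25
    frac_well_responders: float = 11 / 25
    repertoire_depth: int = 100_000
    n_clones: int = 1000
    powerlaw_exponent: float = 1.0
    nonproductive_frac: float = 0.0
    # ITC structure: responder-dependent overlap, mirroring the reported contrast
    itc_overlap_frac: float = 0.44
    itc_overlap_frac_poor: float = 0.20
    frac_expanded: float = 0.25
    frac_contracted: float = 0.65
    expansion_factor_well: float = 5.0
    expansion_factor_poor: float = 1.5
    frac_new_clones: float = 0.5
    new_space_frac: float = 0.30
    # expression / signature structure
    n_genes: int = 2000
    genes_per_hallmark: int = 30
    signature_effect_size: float = 2.0
    n_signature_genes: int = 6
    subtype_effect_size: float = 2.0
    subtype_proportions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    # neoantigens / TCR pairs
    n_neoantigens: int = 50
    binder_rank_max: float = 2.0
    binder_enrichment_well: float = 0.30
    binder_enrichment_poor: float = 0.10
    # clinical / survival
    n_historical: int = 50
    arm_hazard_ratio: float = 1.0
    stage_log_hazard: float = 0.8
    confounding_log_odds: float = 1.2
    baseline_hazard: float = 0.02  # events per month
    followup_months: tuple[float, float] = (24.0, 36.0)
    seed: int = 0

    def validate(self) -> "CohortConfig":
        proportions = [
            ("frac_well_responders", self.frac_well_responders),
            ("nonproductive_frac", self.nonproductive_frac),
            ("itc_overlap_frac", self.itc_overlap_frac),
            ("itc_overlap_frac_poor", self.itc_overlap_frac_poor),
            ("frac_expanded", self.frac_expanded),
            ("frac_contracted", self.frac_contracted),
            ("frac_new_clones", self.frac_new_clones),
            ("new_space_frac", self.new_space_frac),
        ]
        for name, value in proportions:
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {value}")
        if self.frac_expanded + self.frac_contracted > 1.0 + 1e-9:
            raise ConfigurationError("frac_expanded + frac_contracted must not exceed 1")
        if abs(sum(self.subtype_proportions) - 1.0) > 1e-9:
            raise ConfigurationError("subtype_proportions must sum to 1")
        if min(self.subtype_proportions) < 0:
            raise ConfigurationError("subtype_proportions must be non-negative")
        for name in ("n_patients", "repertoire_depth", "n_clones", "n_genes", "n_neoantigens"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.powerlaw_exponent <= 0:
            raise ConfigurationError("powerlaw_exponent must be positive")
        if min(self.expansion_factor_well, self.expansion_factor_poor) <= 0:
            raise ConfigurationError("expansion factors must be positive")
        return self


@dataclass
class GroundTruth:
    """Planted truth for one generated artefact (or a whole cohort)."""

    responder: dict = field(default_factory=dict)          # patient -> "well" | "poor"
    clone_category: dict = field(default_factory=dict)     # key -> expanded/contracted/stable/new/lost
    signature_genes: dict = field(default_factory=dict)    # gene -> "up_well" | "up_poor"
    tme_subtype: dict = field(default_factory=dict)        # patient -> subtype
    true_binder: dict = field(default_factory=dict)        # (patient, clonotype, peptide) -> bool
    extras: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        def _encode(d):
            return {"|".join(map(str, k)) if isinstance(k, tuple) else str(k): v for k, v in d.items()}

        payload = {
            "responder": _encode(self.responder),
            "clone_category": _encode(self.clone_category),
            "signature_genes": _encode(self.signature_genes),
            "tme_subtype": _encode(self.tme_subtype),
            "true_binder": _encode(self.true_binder),
            "extras": self.extras,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# repertoires
# ---------------------------------------------------------------------------

def powerlaw_frequencies(n_clones: int, exponent: float) -> np.ndarray:
    """Truncated power-law rank-frequency profile, normalised to sum 1."""
    ranks = np.arange(1, n_clones + 1, dtype=float)
    p = ranks ** (-float(exponent))
    return p / p.sum()


def _random_cdr3aa(rng: np.random.Generator) -> str:
    length = int(rng.integers(8, 19))
    middle = "".join(rng.choice(list(AA_ALPHABET), size=length - 2))
    return "C" + middle + ("F" if rng.random() < 0.8 else "W")


def _random_nonproductive(rng: np.random.Generator) -> str:
    base = _random_cdr3aa(rng)
    mode = rng.integers(0, 3)
    if mode == 0:
        i = int(rng.integers(1, len(base) - 1))
        return base[:i] + "*" + base[i + 1:]
    if mode == 1:
        return base[:-1] + "_"
    return base[1:4]  # too short and no leading C


def _make_clone_records(rng: np.random.Generator, n: int, nonproductive_frac: float = 0.0) -> pd.DataFrame:
    seen: set[str] = set()
    aa = []
    n_bad = int(round(nonproductive_frac * n))
    for i in range(n):
        while True:
            s = _random_nonproductive(rng) if i < n_bad else _random_cdr3aa(rng)
            if s not in seen:
                seen.add(s)
                aa.append(s)
                break
    nt = ["".join(rng.choice(list("ACGT"), size=3 * len(s))) for s in aa]
    df = pd.DataFrame(
        {
            "count": np.zeros(n, dtype=int),
            "freq": 0.0,
            "cdr3nt": nt,
            "cdr3aa": aa,
            "v": rng.choice(V_GENES, size=n),
            "d": rng.choice(D_GENES, size=n),
            "j": rng.choice(J_GENES, size=n),
        }
    )
    if nonproductive_frac > 0:
        df["planted_nonproductive"] = np.arange(n) < n_bad
    return df


def _sample_counts(rng: np.random.Generator, depth: int, p: np.ndarray) -> np.ndarray:
    """Multinomial counts that keep every clone present (each clone gets one template
    up front, the rest of the depth is multinomial)."""
    n = len(p)
    return 1 + rng.multinomial(depth - n, p)


def generate_repertoire(
    n_clones: int,
    depth: int,
    exponent: float = 1.0,
    seed: int = 0,
    patient: str | None = None,
    compartment: str = "tumor",
    timepoint: str = "baseline",
    nonproductive_frac: float = 0.0,
) -> ClonotypeTable:
    """One repertoire sample: power-law clone profile, multinomial counts at ``depth``.

    Counts sum exactly to ``depth`` and all ``n_clones`` clonotypes are present.
    A ``nonproductive_frac`` fraction of CDR3aa strings deliberately violates the
    productive grammar (labelled in a ``planted_nonproductive`` column) for QC tests.
    """
    if n_clones < 1 or depth < n_clones:
        raise ConfigurationError(f"need n_clones >= 1 and depth >= n_clones, got {n_clones}, {depth}")
    rng = stream_rng(seed, f"repertoire/{patient}/{compartment}/{timepoint}")
    df = _make_clone_records(rng, n_clones, nonproductive_frac)
    p = powerlaw_frequencies(n_clones, exponent)
    df["count"] = _sample_counts(rng, depth, p)
    return ClonotypeTable(df, patient=patient, compartment=compartment, timepoint=timepoint)


def generate_paired_tumor_repertoires(
    config: CohortConfig,
    responder: str = "well",
    seed: int = 0,
    patient: str = "P01",
) -> tuple[ClonotypeTable, ClonotypeTable, GroundTruth]:
    """Paired pre/post tumour repertoires with planted clonal dynamics.

    Persistent clones are drawn frequency-weighted (high-frequency clones are more
    likely to persist).  Among them a ``frac_expanded`` fraction is multiplied by the
    responder's expansion factor and a ``frac_contracted`` fraction is scaled down so
    that total probability still sums to one while *stable* clones keep exactly their
    pre-treatment probability; new clones receive ``new_space_frac`` of the freed
    clonal space.  Post counts are then multinomial at the configured depth.
    """
    config.validate()
    if responder not in ("well", "poor"):
        raise ConfigurationError(f"responder must be 'well' or 'poor', got {responder!r}")
    rng = stream_rng(seed, f"paired/{patient}/{responder}")
    n = config.n_clones
    depth = config.repertoire_depth

    pre_df = _make_clone_records(rng, n, config.nonproductive_frac)
    p_pre = powerlaw_frequencies(n, config.powerlaw_exponent)
    pre_df["count"] = _sample_counts(rng, depth, p_pre)
    pre = ClonotypeTable(pre_df, patient=patient, compartment="tumor", timepoint="baseline")

    overlap = config.itc_overlap_frac if responder == "well" else config.itc_overlap_frac_poor
    factor = config.expansion_factor_well if responder == "well" else config.expansion_factor_poor
    n_persist = int(round(overlap * n))
    if n_persist > 0:
        persist_idx = rng.choice(n, size=n_persist, replace=False, p=p_pre)
    else:
        persist_idx = np.array([], dtype=int)
    # dominant persistent clones contract (exhausted), the rarest expand; this also
    # keeps the expanded clonal space small enough to multiply by the factor
    persist_idx = persist_idx[np.argsort(-p_pre[persist_idx], kind="stable")]
    n_exp = int(round(config.frac_expanded * n_persist))
    n_con = int(round(config.frac_contracted * n_persist))
    contracted_idx = persist_idx[:n_con]
    stable_idx = persist_idx[n_con:n_persist - n_exp]
    expanded_idx = persist_idx[n_persist - n_exp:] if n_exp else persist_idx[:0]

    n_new = int(round(config.frac_new_clones * n))
    new_df = _make_clone_records(rng, n_new, 0.0) if n_new else pre_df.iloc[:0].copy()

    mass_stable = p_pre[stable_idx].sum()
    mass_expanded = factor * p_pre[expanded_idx].sum()
    free = 1.0 - mass_stable - mass_expanded
    if free <= 0:
        raise ConfigurationError(
            "expanded + stable clonal space exceeds 1; lower expansion_factor or frac_expanded"
        )
    mass_new = config.new_space_frac * free if n_new else 0.0
    mass_contracted_target = free - mass_new
    pre_contracted_mass = p_pre[contracted_idx].sum()
    if len(contracted_idx) and pre_contracted_mass > 0:
        # contraction, never expansion: cap the scale at 1
        scale = min(mass_contracted_target / pre_contracted_mass, 1.0)
    else:
        scale = 0.0
    # whatever the contracted set does not absorb goes to the new clones
    mass_new = free - scale * pre_contracted_mass

    p_post_old = np.zeros(n)
    p_post_old[stable_idx] = p_pre[stable_idx]
    p_post_old[expanded_idx] = factor * p_pre[expanded_idx]
    p_post_old[contracted_idx] = scale * p_pre[contracted_idx]
    if n_new:
        p_new = powerlaw_frequencies(n_new, config.powerlaw_exponent) * mass_new
    else:
        p_new = np.array([])

    post_df = pd.concat([pre_df.iloc[persist_idx], new_df], ignore_index=True)
    p_post = np.concatenate([p_post_old[persist_idx], p_new])
    p_post = p_post / p_post.sum()
    post_df["count"] = _sample_counts(rng, depth, p_post) if len(post_df) else 0
    post = ClonotypeTable(post_df, patient=patient, compartment="tumor", timepoint="post_surgery")

    def _keys(df: pd.DataFrame) -> list:
        return list(zip(df["cdr3aa"], df["v"], df["j"]))

    pre_keys = _keys(pre_df)
    truth = GroundTruth(responder={patient: responder})
    for i in expanded_idx:
        truth.clone_category[pre_keys[i]] = "expanded"
    for i in contracted_idx:
        truth.clone_category[pre_keys[i]] = "contracted"
    for i in stable_idx:
        truth.clone_category[pre_keys[i]] = "stable"
    persist_set = set(persist_idx.tolist())
    for i in range(n):
        if i not in persist_set:
            truth.clone_category[pre_keys[i]] = "lost"
    for k in _keys(new_df):
        truth.clone_category[k] = "new"
    truth.extras["expansion_factor"] = factor
    truth.extras["contraction_scale"] = scale
    truth.extras["pre_freq"] = {pre_keys[i]: float(p_pre[i]) for i in range(n)}
    return pre, post, truth


def generate_blood_series(
    itcs: Mapping,
    timepoints: Sequence[str],
    dynamics: Sequence[float],
    seed: int = 0,
    patient: str | None = None,
    circulating_frac: float = 0.5,
    n_background: int = 500,
    depth: int = 50_000,
    exponent: float = 1.0,
) -> list[ClonotypeTable]:
    """Longitudinal blood repertoires seeding a subset of ITC clones.

    ``itcs`` maps clonotype keys ``(cdr3aa, v, j)`` to their baseline blood
    frequency; ``dynamics`` gives one multiplicative scale factor per timepoint
    (e.g. a W6 peak).  A power-law background of ``n_background`` clones fills the
    rest of each repertoire.
    """
    if not timepoints:
        raise ConfigurationError("timepoints must be non-empty")
    if len(dynamics) != len(timepoints):
        raise ConfigurationError("dynamics must give one scale factor per timepoint")
    if not 0.0 <= circulating_frac <= 1.0:
        raise ConfigurationError("circulating_frac must lie in [0, 1]")
    rng = stream_rng(seed, f"blood/{patient}")
    keys = list(itcs)
    n_circ = int(round(circulating_frac * len(keys)))
    circ_keys = [keys[i] for i in rng.choice(len(keys), size=n_circ, replace=False)] if n_circ else []
    base_freq = np.array([itcs[k] for k in circ_keys], dtype=float)

    bg_df = _make_clone_records(rng, n_background, 0.0)
    bg_p = powerlaw_frequencies(n_background, exponent)

    tables = []
    for tp, scale in zip(timepoints, dynamics):
        circ_p = np.clip(base_freq * float(scale), 0.0, None)
        total_circ = circ_p.sum()
        if total_circ >= 0.9:  # keep a background floor
            circ_p = circ_p * (0.9 / total_circ)
            total_circ = 0.9
        p = np.concatenate([circ_p, bg_p * (1.0 - total_circ)])
        if circ_keys:
            circ_df = pd.DataFrame(
                {
                    "count": 0,
                    "freq": 0.0,
                    "cdr3nt": ".",
                    "cdr3aa": [k[0] for k in circ_keys],
                    "v": [k[1] for k in circ_keys],
                    "d": ".",
                    "j": [k[2] for k in circ_keys],
                }
            )
            df = pd.concat([circ_df, bg_df], ignore_index=True)
        else:
            df = bg_df.copy()
        df["count"] = _sample_counts(rng, depth, p / p.sum())
        tables.append(ClonotypeTable(df, patient=patient, compartment="blood", timepoint=tp))
    return tables


# ---------------------------------------------------------------------------
# expression, gene sets, clinical, neoantigens
# ---------------------------------------------------------------------------

def hallmark_gene_sets(config: CohortConfig) -> dict[str, list[str]]:
    """Deterministic synthetic hallmark gene sets (no randomness: derived from config only)."""
    sets = {}
    for name in ALL_HALLMARKS:
        short = name.replace("HALLMARK_", "")[:12]
        sets[name] = [f"{short}_G{i:03d}" for i in range(1, config.genes_per_hallmark + 1)]
    return sets


def signature_gene_sets(config: CohortConfig) -> dict[str, list[str]]:
    """The three candidate-gene sets for the IFN/EMT signature (subsets of the hallmarks)."""
    sets = hallmark_gene_sets(config)
    return {
        "EMT": sets["HALLMARK_EPITHELIAL_MESENCHYMAL_TRANSITION"],
        "IFN_ALPHA": sets["HALLMARK_INTERFERON_ALPHA_RESPONSE"],
        "IFN_GAMMA": sets["HALLMARK_INTERFERON_GAMMA_RESPONSE"],
    }


def generate_hallmark_scores(
    n_samples: int = 30,
    shift: float = 2.0,
    proportions: Sequence[float] = (1 / 3, 1 / 3, 1 / 3),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Hallmark-score matrix (13 x n) with three planted subtypes.

    Each sample gets iid standard-normal hallmark scores plus ``shift`` (in z-units)
    on the hallmarks of its subtype's marker group.  Returns (scores, true labels).
    """
    if abs(sum(proportions) - 1.0) > 1e-9 or min(proportions) < 0:
        raise ConfigurationError("proportions must be non-negative and sum to 1")
    rng = stream_rng(seed, "hallmark_scores")
    counts = np.floor(np.asarray(proportions) * n_samples).astype(int)
    while counts.sum() < n_samples:
        counts[int(np.argmax(np.asarray(proportions) * n_samples - counts))] += 1
    labels = np.repeat(list(SUBTYPES), counts)
    samples = [f"S{i + 1:02d}" for i in range(n_samples)]
    scores = pd.DataFrame(
        rng.normal(size=(len(ALL_HALLMARKS), n_samples)), index=ALL_HALLMARKS, columns=samples
    )
    for j, lab in enumerate(labels):
        scores.loc[HALLMARK_GROUPS[lab], samples[j]] += shift
    return scores, pd.Series(labels, index=samples, name="subtype")


def generate_signature_recovery_problem(
    n_well: int = 9,
    n_poor: int = 9,
    n_decoys: int = 131,
    n_planted: int = 3,
    effect: float = 2.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Candidate-gene matrix with a few informative genes among many decoys.

    Planted genes are shifted by ``effect`` log2 units in well responders on unit
    normal noise; decoys are pure noise.  Returns (matrix, labels, planted genes).
    """
    rng = stream_rng(seed, "signature_recovery")
    samples = [f"W{i}" for i in range(n_well)] + [f"Q{i}" for i in range(n_poor)]
    labels = pd.Series(["well"] * n_well + ["poor"] * n_poor, index=samples)
    planted = [f"PLANTED_{i}" for i in range(n_planted)]
    decoys = [f"DECOY_{i:03d}" for i in range(n_decoys)]
    base = rng.uniform(2.0, 8.0, size=n_planted + n_decoys)
    values = base[:, None] + rng.normal(size=(n_planted + n_decoys, n_well + n_poor))
    matrix = pd.DataFrame(values, index=planted + decoys, columns=samples)
    matrix.loc[planted, labels == "well"] += effect
    return matrix.clip(lower=0.0), labels, planted


def _patient_labels(config: CohortConfig) -> tuple[list[str], dict[str, str]]:
    patients = [f"P{i + 1:02d}" for i in range(config.n_patients)]
    n_well = int(round(config.frac_well_responders * config.n_patients))
    responder = {p: ("well" if i < n_well else "poor") for i, p in enumerate(patients)}
    return patients, responder


def generate_expression_and_clinical(
    config: CohortConfig, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Expression matrix, clinical table, neoantigen table, TCR-pair table + truth.

    Expression is log2(FPKM+1)-scale: per-gene baseline means Uniform(1, 8) with unit
    normal noise, clipped at 0.  Planted effects: ``signature_effect_size`` on
    ``n_signature_genes`` IFN genes (up in well responders) and the same number of
    EMT genes (up in poor responders); ``subtype_effect_size`` on each subtype's
    hallmark-group genes.  Survival is exponential with a stage effect and a
    stage-confounded two-arm assignment (trial vs historical); the arm effect is
    ``arm_hazard_ratio`` (1.0 = null).
    """
    config.validate()
    rng = stream_rng(seed, "expression")
    patients, responder = _patient_labels(config)
    hallmarks = hallmark_gene_sets(config)
    set_union: list[str] = []
    for genes in hallmarks.values():
        set_union.extend(genes)
    named = MARKER_GENES + set_union
    if config.n_genes < len(named):
        raise ConfigurationError(
            f"n_genes={config.n_genes} is smaller than the union of planted gene sets ({len(named)})"
        )
    filler = [f"G{i:05d}" for i in range(1, config.n_genes - len(named) + 1)]
    genes = named + filler

    base = rng.uniform(1.0, 8.0, size=len(genes))
    expr = base[:, None] + rng.normal(scale=1.0, size=(len(genes), len(patients)))
    expr = np.clip(expr, 0.0, None)
    matrix = pd.DataFrame(expr, index=genes, columns=patients)

    # planted IFN/EMT signature genes
    sig_sets = signature_gene_sets(config)
    truth = GroundTruth(responder=dict(responder))
    ifn_genes = sig_sets["IFN_GAMMA"][: config.n_signature_genes]
    emt_genes = sig_sets["EMT"][: config.n_signature_genes]
    well_cols = [p for p in patients if responder[p] == "well"]
    poor_cols = [p for p in patients if responder[p] == "poor"]
    matrix.loc[ifn_genes, well_cols] += config.signature_effect_size
    matrix.loc[emt_genes, poor_cols] += config.signature_effect_size
    for g in ifn_genes:
        truth.signature_genes[g] = "up_well"
    for g in emt_genes:
        truth.signature_genes[g] = "up_poor"

    # planted TME subtypes (IE enriched among well responders)
    rng_sub = stream_rng(seed, "subtypes")
    subtype: dict[str, str] = {}
    base_p = np.asarray(config.subtype_proportions, dtype=float)
    # responder-conditional tilt: IE over-represented in well responders (multiplicative,
    # so degenerate configurations like (1, 0, 0) stay degenerate)
    tilt = {"well": np.array([3.0, 1.0, 1.0]), "poor": np.array([0.3, 1.2, 1.2])}
    for p in patients:
        probs = base_p * tilt[responder[p]]
        subtype[p] = SUBTYPES[rng_sub.choice(3, p=probs / probs.sum())]
    for p in patients:
        for h in HALLMARK_GROUPS[subtype[p]]:
            matrix.loc[hallmarks[h], p] += config.subtype_effect_size
    truth.tme_subtype = subtype
    matrix = matrix.clip(lower=0.0)

    clinical = _generate_clinical(config, seed, patients, responder)
    neo, pairs = _generate_neoantigens(config, seed, patients, responder, truth)
    return matrix, clinical, neo, pairs, truth


def _generate_clinical(
    config: CohortConfig, seed: int, patients: list[str], responder: dict[str, str]
) -> pd.DataFrame:
    """Two-arm clinical table: trial patients plus a stage-confounded historical arm."""
    rng = stream_rng(seed, "clinical")
    n_hist = config.n_historical
    hist = [f"H{i + 1:03d}" for i in range(n_hist)]
    all_ids = patients + hist

    rows = []
    stage_levels = np.array([0.0, 1.0, 2.0])  # II, III, IV
    base_stage_p = np.array([0.25, 0.6, 0.15])
    for pid in all_ids:
        trial = pid.startswith("P")
        arm = "nAde" if trial else "historical"
        # arm-conditional stage distribution (the planted confounding): higher stages
        # are over-represented in the historical arm
        sign = -0.5 if trial else 0.5
        w = base_stage_p * np.exp(sign * config.confounding_log_odds * (stage_levels - 1.0))
        stage_idx = int(rng.choice(3, p=w / w.sum()))
        site = SITES[int(rng.choice(3, p=[0.12, 0.44, 0.44]))]
        if trial:
            if responder[pid] == "well":
                residual = float(rng.choice([0.0, rng.uniform(0.0, 33.0)], p=[0.2, 0.8]))
            else:
                residual = float(rng.uniform(34.0, 95.0))
        else:
            residual = float(rng.uniform(0.0, 95.0))
        hazard = config.baseline_hazard * np.exp(
            config.stage_log_hazard * (stage_levels[stage_idx] - 1.0)
            + (np.log(config.arm_hazard_ratio) if arm == "nAde" else 0.0)
        )
        event_time = rng.exponential(1.0 / hazard)
        censor_time = rng.uniform(*config.followup_months)
        os_time = min(event_time, censor_time)
        rows.append(
            {
                "patient": pid,
                "arm": arm,
                "stage": STAGES[stage_idx],
                "site": site,
                "residual_tumor_percent": round(residual, 1),
                "os_time": round(float(max(os_time, 0.01)), 3),
                "os_event": bool(event_time <= censor_time),
                "rfs_time": round(float(max(os_time * rng.uniform(0.6, 1.0), 0.01)), 3),
                "rfs_event": bool(event_time <= censor_time),
            }
        )
    return pd.DataFrame(rows)


def _generate_neoantigens(
    config: CohortConfig,
    seed: int,
    patients: list[str],
    responder: dict[str, str],
    truth: GroundTruth,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    rng = stream_rng(seed, "neoantigens")
    neo_rows, pair_rows = [], []
    for pid in patients:
        well = responder[pid] == "well"
        # mutation persistence: well responders clear more mutations
        p_class = [0.5, 0.15, 0.35] if well else [0.25, 0.25, 0.5]  # clearance, novel, persistent
        enrich = config.binder_enrichment_well if well else config.binder_enrichment_poor
        for i in range(config.n_neoantigens):
            cls = ["clearance", "novel", "persistent"][int(rng.choice(3, p=p_class))]
            peptide = "".join(rng.choice(list(AA_ALPHABET), size=9))
            affinity = float(10 ** rng.uniform(1.0, 3.7))  # 10 nM .. ~5000 nM
            mut = f"{pid}_MUT{i:03d}"
            neo_rows.append(
                {
                    "patient": pid,
                    "peptide": peptide,
                    "allele": f"HLA-A*{int(rng.integers(1, 34)):02d}:01",
                    "affinity_nm": round(affinity, 2),
                    "mutation_key": mut,
                    "pre": cls in ("clearance", "persistent"),
                    "post": cls in ("novel", "persistent"),
                    "nonsynonymous": True,
                }
            )
            for t in range(3):  # a few candidate TCR pairings per neoantigen
                clone = f"CLONE_{pid}_{int(rng.integers(0, 200)):03d}"
                binder = rng.random() < enrich
                rank = float(rng.uniform(0.0, config.binder_rank_max)) if binder else float(
                    rng.uniform(config.binder_rank_max, 100.0)
                )
                pair_rows.append(
                    {
                        "patient": pid,
                        "clonotype": clone,
                        "peptide": peptide,
                        "percentile_rank": round(max(rank, 1e-6), 4),
                    }
                )
                truth.true_binder[(pid, clone, peptide)] = bool(binder)
    return pd.DataFrame(neo_rows), pd.DataFrame(pair_rows)


def generate_confounded_survival(
    n: int = 200,
    arm_hazard_ratio: float = 1.0,
    stage_log_hazard: float = 0.8,
    confounding_log_odds: float = 1.2,
    baseline_hazard: float = 0.05,
    censor_months: tuple[float, float] = (24.0, 36.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Minimal two-arm survival cohort with a stage confounder, for IPTW studies.

    Stage shifts both the hazard (``stage_log_hazard`` per level) and the arm
    assignment odds (``confounding_log_odds``), so with a null arm effect the
    unadjusted arms still differ in survival.
    """
    rng = stream_rng(seed, "confounded_survival")
    stage_idx = rng.choice(3, size=n, p=[0.25, 0.6, 0.15])
    centred = stage_idx - 1.0
    p_a = 1.0 / (1.0 + np.exp(confounding_log_odds * centred))
    arm = np.where(rng.random(n) < p_a, "A", "B")
    hazard = baseline_hazard * np.exp(
        stage_log_hazard * centred + np.where(arm == "A", np.log(arm_hazard_ratio), 0.0)
    )
    event_time = rng.exponential(1.0 / hazard)
    censor = rng.uniform(*censor_months, size=n)
    site = np.array(SITES)[rng.choice(3, size=n, p=[0.12, 0.44, 0.44])]
    return pd.DataFrame(
        {
            "patient": [f"X{i:04d}" for i in range(n)],
            "arm": arm,
            "stage": np.array(STAGES)[stage_idx],
            "site": site,
            "os_time": np.maximum(np.minimum(event_time, censor), 1e-3),
            "os_event": event_time <= censor,
        }
    )


# ---------------------------------------------------------------------------
# cohort assembly and on-disk layout
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """A fully generated synthetic cohort, ready for the analysis pipeline."""

    config: CohortConfig
    repertoires: dict            # (patient, compartment, timepoint) -> ClonotypeTable
    expression: pd.DataFrame
    clinical: pd.DataFrame
    neoantigens: pd.DataFrame
    tcr_pairs: pd.DataFrame
    truth: GroundTruth


def generate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> Cohort:
    """Generate the complete cohort: paired tumours, blood series and all tables."""
    config = (config or CohortConfig()).validate()
    seed = config.seed if seed is None else seed
    patients, responder = _patient_labels(config)
    expression, clinical, neo, pairs, truth = generate_expression_and_clinical(config, seed)
    repertoires = {}
    for i, pid in enumerate(patients):
        pre, post, pt_truth = generate_paired_tumor_repertoires(
            config, responder=responder[pid], seed=seed + i + 1, patient=pid
        )
        repertoires[(pid, "tumor", "baseline")] = pre
        repertoires[(pid, "tumor", "post_surgery")] = post
        truth.clone_category.update(
            {(pid,) + k: v for k, v in pt_truth.clone_category.items()}
        )
        # ITC clones are seeded into blood at ~5% of their intratumoral frequency
        itc_keys = {
            k: 0.05 * f for k, f in pt_truth.extras["pre_freq"].items()
            if pt_truth.clone_category.get(k) in ("expanded", "contracted", "stable")
        }
        blood = generate_blood_series(
            itc_keys,
            timepoints=["baseline", "W3", "W6"],
            dynamics=[1.0, 1.8, 3.0] if responder[pid] == "well" else [1.0, 1.0, 1.0],
            seed=seed + i + 1,
            patient=pid,
            depth=min(config.repertoire_depth, 50_000),
        )
        for table in blood:
            repertoires[(pid, "blood", table.timepoint)] = table
    return Cohort(config, repertoires, expression, clinical, neo, pairs, truth)


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write the cohort in the plain-text formats the analysis CLI consumes."""
    outdir = Path(outdir)
    (outdir / "repertoires").mkdir(parents=True, exist_ok=True)
    sheet = []
    for (pid, compartment, timepoint), table in cohort.repertoires.items():
        rel = f"repertoires/{pid}_{compartment}_{timepoint}.tsv"
        write_clonotype_table(table, outdir / rel)
        sheet.append({"patient": pid, "compartment": compartment, "timepoint": timepoint, "path": rel})
    pd.DataFrame(sheet).to_csv(outdir / "sample_sheet.tsv", sep="\t", index=False)
    cohort.expression.to_csv(outdir / "expression.tsv", sep="\t", index_label="gene")
    cohort.clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
    cohort.neoantigens.to_csv(outdir / "neoantigens.tsv", sep="\t", index=False)
    # MAF-like per-timepoint mutation table derived from the neoantigen sources
    muts = cohort.neoantigens[
        ["patient", "mutation_key", "pre", "post", "nonsynonymous"]
    ].drop_duplicates()
    muts.to_csv(outdir / "mutations.tsv", sep="\t", index=False)
    cohort.tcr_pairs.to_csv(outdir / "tcr_pairs.tsv", sep="\t", index=False)
    from .signatures import write_gmt  # local import to avoid a cycle

    write_gmt(hallmark_gene_sets(cohort.config), outdir / "hallmarks.gmt")
    write_gmt(signature_gene_sets(cohort.config), outdir / "signature_sets.gmt")
    cohort.truth.to_json(outdir / "ground_truth.json")
    (outdir / "config.json").write_text(json.dumps(dataclasses.asdict(cohort.config), indent=1))
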