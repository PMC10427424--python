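"""Expression-based immune scores, ssGSEA hallmark scoring and the IFN/EMT signature.

All operators take a genes x samples matrix of log2(FPKM+1) values.

The formula-defined scores are arithmetic means of marker-gene expression (CD8
lineage, exhausted, chemokine, HLA-II, DC), the geometric mean of GZMA/PRF1 on the
linear scale (cytolytic activity), and a configurable sum of cell scores (TIL
score).

ssGSEA follows the single-sample running-sum formulation: per sample, genes are
ranked by expression (descending, ties by average rank); the enrichment score is
the sum over all ranked positions of the difference between the weighted in-set
empirical CDF (weights rank^exponent, exponent 0.25 by default) and the out-of-set
CDF.  Scores are then normalised by the global (max - min) across all sets and
samples; a per-set z-score clipped to [-2, 2] gives the presentation scale.

The IFN/EMT signature is an elastic-net linear model (mixing alpha = 0.5, penalty
lambda = 0.24, loss scaled by 1/(2n), predictors standardised to unit variance,
response 1 = well / 0 = poor responder) fitted on candidate genes: members of the
EMT / IFN-alpha / IFN-gamma gene sets whose group means differ by at least one
log2 unit (two-fold on the linear scale, boundary inclusive).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import ElasticNet, LinearRegression

from .errors import DataError, EmptyModelError, UsageError

#: documented alias map applied on load (the literature contains typographical
#: variants of some symbols)
GENE_ALIASES: Mapping[str, str] = {"CXLC9": "CXCL9"}

#: formula-defined marker gene sets
MARKER_SETS: Mapping[str, list[str]] = {
    "cd8_lineage": ["CD2", "CD3D", "CD3E", "CD8A", "CD8B"],
    "exhausted": ["CD274", "HAVCR2", "TNFRSF9", "CTLA4", "TOX"],
    "chemokine": ["GZMB", "CXCL9", "CXCL10", "CCL5"],
    "hla_ii": [
        "HLA-DRA", "HLA-DRB1", "HLA-DRB2", "HLA-DRB3", "HLA-DRB4", "HLA-DRB5",
        "HLA-DQA1", "HLA-DQA2", "HLA-DQB1", "HLA-DQB2", "HLA-DPA1", "HLA-DPB1",
    ],
    "dc": ["FLT3", "CLEC9A", "XCR1"],
}

#: default components of the TIL score (a configurable sum of cell scores)
DEFAULT_TIL_COMPONENTS = [
    "cd45_t", "cd8_t", "cytotoxic_cd8_t", "exhausted_cd8_t", "th1", "treg", "b_cells",
]


def _canonical_symbol(symbol: str) -> str:
    s = str(symbol).strip().upper()
    return GENE_ALIASES.get(s, s)


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file; symbols are upper-cased and alias-mapped."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise DataError(f"GMT line with fewer than 3 fields: {line[:50]!r}")
        name, _desc, *genes = fields
        genes = [_canonical_symbol(g) for g in genes if g]
        if not genes:
            raise DataError(f"gene set {name!r} is empty")
        sets[name] = genes
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path) -> None:
    lines = [f"{name}\tna\t" + "\t".join(genes) for name, genes in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples TSV of log2(FPKM+1) values (first column = gene symbol)."""
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    matrix.index = [_canonical_symbol(g) for g in matrix.index]
    if matrix.index.duplicated().any():
        dupes = matrix.index[matrix.index.duplicated()][:5].tolist()
        raise DataError(f"duplicate gene symbols in expression matrix: {dupes}")
    if matrix.isna().any().any():
        raise DataError("expression matrix contains missing values")
    return matrix


# ---------------------------------------------------------------------------
# formula scores
# ---------------------------------------------------------------------------

def mean_signature_score(matrix: pd.DataFrame, gene_list: Sequence[str]) -> pd.Series:
    """Arithmetic mean of log2 expression over the listed genes (per sample).

    Genes absent from the matrix are dropped with a warning; if none remain an
    error lists the missing symbols.
    """
    wanted = [_canonical_symbol(g) for g in gene_list]
    present = [g for g in wanted if g in matrix.index]
    missing = [g for g in wanted if g not in matrix.index]
    if not present:
        raise DataError(f"none of the signature genes are in the matrix: {missing}")
    if missing:
        warnings.warn(f"signature genes missing from matrix: {missing}", stacklevel=2)
    return matrix.loc[present].mean(axis=0)


def marker_scores(matrix: pd.DataFrame) -> pd.DataFrame:
    """All mean-expression marker scores plus cytolytic activity, samples x scores."""
    out = {name: mean_signature_score(matrix, genes) for name, genes in MARKER_SETS.items()}
    out["cytolytic_activity"] = cytolytic_activity(matrix)
    return pd.DataFrame(out)


def cytolytic_activity(matrix: pd.DataFrame) -> pd.Series:
    """Geometric mean of GZMA and PRF1 on the linear expression scale (2^x - 1)."""
    for gene in ("GZMA", "PRF1"):
        if gene not in matrix.index:
            raise DataError(f"cytolytic activity requires gene {gene}, absent from matrix")
    linear = np.power(2.0, matrix.loc[["GZMA", "PRF1"]]) - 1.0
    return np.sqrt(linear.loc["GZMA"] * linear.loc["PRF1"])


def til_score(cell_scores: pd.DataFrame, components: Sequence[str] = DEFAULT_TIL_COMPONENTS) -> pd.Series:
    """TIL score: sum of the configured cell-score columns (samples x scores input)."""
    missing = [c for c in components if c not in cell_scores.columns]
    if missing:
        raise DataError(f"cell-score table lacks components: {missing}")
    return cell_scores[list(components)].sum(axis=1)


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------

def ssgsea(
    matrix: pd.DataFrame,
    gene_sets: Mapping[str, Sequence[str]],
    weight_exponent: float = 0.25,
    normalize: bool = True,
) -> pd.DataFrame:
    """Single-sample GSEA enrichment scores, sets x samples.

    Per sample: genes ranked by expression descending (ties by average rank); the
    running sum accumulates the rank^exponent-weighted in-set ECDF minus the
    uniform out-of-set ECDF, and the enrichment score is the sum of that running
    difference over all positions.  With ``normalize`` the whole score matrix is
    divided by its (max - min) across all sets and samples.
    """
    genes = matrix.index
    n_genes = len(genes)
    memberships = {}
    for name, members in gene_sets.items():
        members = {_canonical_symbol(g) for g in members}
        mask = np.asarray(genes.isin(members))
        m = int(mask.sum())
        if m == 0:
            raise DataError(f"gene set {name!r} has no members in the matrix")
        if m >= n_genes:
            raise DataError(f"gene set {name!r} covers every gene; out-of-set ECDF undefined")
        memberships[name] = mask

    scores = np.zeros((len(memberships), matrix.shape[1]))
    values = matrix.to_numpy(dtype=float)
    for j in range(matrix.shape[1]):
        col = values[:, j]
        ranks = rankdata(col)  # ascending, ties -> average rank
        order = np.lexsort((np.arange(n_genes), -ranks))  # descending, deterministic
        weights = ranks[order] ** float(weight_exponent)
        for i, (name, mask) in enumerate(memberships.items()):
            in_set = mask[order]
            w_in = np.where(in_set, weights, 0.0)
            cdf_in = np.cumsum(w_in) / w_in.sum()
            out = (~in_set).astype(float)
            cdf_out = np.cumsum(out) / out.sum()
            scores[i, j] = float(np.sum(cdf_in - cdf_out))
    result = pd.DataFrame(scores, index=list(memberships), columns=matrix.columns)
    if normalize:
        spread = float(result.to_numpy().max() - result.to_numpy().min())
        if spread > 0:
            result = result / spread
    return result


def scale_hallmark_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-hallmark z-score across samples, clipped to [-2, 2].

    Zero-variance hallmarks become all-zero rows (with a warning).
    """
    if scores.shape[1] < 2:
        raise UsageError("scaling requires at least 2 samples")
    mean = scores.mean(axis=1)
    sd = scores.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(f"zero-variance hallmarks set to 0: {list(scores.index[flat])}", stacklevel=2)
    sd = sd.replace(0.0, 1.0)
    z = scores.sub(mean, axis=0).div(sd, axis=0)
    z[flat] = 0.0
    return z.clip(-2.0, 2.0)


# ---------------------------------------------------------------------------
# IFN/EMT elastic-net signature
# ---------------------------------------------------------------------------

def _check_labels(matrix: pd.DataFrame, labels: pd.Series) -> pd.Series:
    labels = pd.Series(labels).reindex(matrix.columns)
    bad = set(labels.dropna().unique()) - {"well", "poor"}
    if bad or labels.isna().any():
        raise UsageError("labels must map every sample to 'well' or 'poor'")
    for group in ("well", "poor"):
        if (labels == group).sum() < 2:
            raise UsageError(f"need at least 2 samples labelled {group!r}")
    return labels


def select_ifn_emt_candidates(
    matrix: pd.DataFrame,
    labels: pd.Series,
    gene_sets: Mapping[str, Sequence[str]],
    min_log2_diff: float = 1.0,
) -> list[str]:
    """Candidate genes: union of the given sets with |group mean difference| >=
    ``min_log2_diff`` log2 units (>= two-fold linear; boundary inclusive)."""
    labels = _check_labels(matrix, labels)
    union: set[str] = set()
    for members in gene_sets.values():
        union |= {_canonical_symbol(g) for g in members}
    present = [g for g in matrix.index if g in union]
    well = matrix.loc[present, labels == "well"].mean(axis=1)
    poor = matrix.loc[present, labels == "poor"].mean(axis=1)
    diff = (well - poor).abs()
    return list(diff.index[diff >= min_log2_diff - 1e-12])


@dataclass
class SignatureModel:
    """A fitted sparse linear signature: genes, weights and frozen standardisation."""

    genes: list[str]
    coefficients: np.ndarray
    intercept: float
    means: np.ndarray
    sds: np.ndarray
    alpha: float
    lam: float

    def score(self, matrix: pd.DataFrame) -> pd.Series:
        """Per-sample signature score using the training-time standardisation."""
        missing = [g for g in self.genes if g not in matrix.index]
        if missing:
            raise DataError(f"matrix lacks signature genes: {missing}")
        x = matrix.loc[self.genes].to_numpy(dtype=float).T
        z = (x - self.means) / self.sds
        return pd.Series(self.intercept + z @ self.coefficients, index=matrix.columns, name="ifn_emt_score")

    def to_json(self, path) -> None:
        payload = {
            "genes": self.genes,
            "coefficients": list(map(float, self.coefficients)),
            "intercept": float(self.intercept),
            "means": list(map(float, self.means)),
            "sds": list(map(float, self.sds)),
            "alpha": self.alpha,
            "lam": self.lam,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "SignatureModel":
        d = json.loads(Path(path).read_text())
        return cls(
            genes=list(d["genes"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            means=np.asarray(d["means"], dtype=float),
            sds=np.asarray(d["sds"], dtype=float),
            alpha=float(d["alpha"]),
            lam=float(d["lam"]),
        )


def fit_ifn_emt_score(
    matrix: pd.DataFrame,
    labels: pd.Series,
    candidates: Sequence[str] | None = None,
    alpha: float = 0.5,
    lam: float = 0.24,
) -> SignatureModel:
    """Fit the elastic-net signature on (candidate-restricted) expression.

    Objective: ``(1/2n) * RSS + lam * (alpha * ||b||_1 + (1-alpha)/2 * ||b||_2^2)``
    with predictors standardised to unit variance and response y = 1 (well) / 0
    (poor).  Only genes with non-zero coefficients are retained in the model.
    """
    labels = _check_labels(matrix, labels)
    if candidates is not None:
        missing = [g for g in candidates if g not in matrix.index]
        if missing:
            raise DataError(f"candidate genes absent from matrix: {missing}")
        matrix = matrix.loc[list(candidates)]
    if matrix.shape[0] < 1:
        raise UsageError("need at least 1 candidate gene")
    if matrix.shape[1] < 4:
        raise UsageError("need at least 4 samples")

    x = matrix.to_numpy(dtype=float).T  # samples x genes
    y = (labels == "well").to_numpy(dtype=float)
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=0)
    if (sds == 0).any():
        flat = list(matrix.index[sds == 0])
        raise DataError(f"zero-variance candidate genes: {flat}")
    z = (x - means) / sds

    if lam == 0:
        fit = LinearRegression().fit(z, y)
        coefs, intercept = fit.coef_, float(fit.intercept_)
    else:
        fit = ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=True, max_iter=100_000, tol=1e-10)
        fit.fit(z, y)
        coefs, intercept = fit.coef_, float(fit.intercept_)

    nonzero = np.flatnonzero(coefs)
    if len(nonzero) == 0:
        raise EmptyModelError(
            f"no gene survives the penalty lam={lam}; lower lam to obtain a non-empty model"
        )
    return SignatureModel(
        genes=[matrix.index[i] for i in nonzero],
        coefficients=coefs[nonzero].copy(),
        intercept=intercept,
        means=means[nonzero].copy(),
        sds=sds[nonzero].copy(),
        alpha=alpha,
        lam=lam,
    )


def apply_signature(matrix: pd.DataFrame, model: SignatureModel) -> pd.Series:
    """Per-sample signature scores with the model's frozen standardisation."""
    return model.score(matrix)
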