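"""Per-coordinate GWAS, LD clumping and locus merging, polygenic scoring,
disease-specific PRS combination, and evaluation.

The association engine is covariate-adjusted per-variant ordinary least
squares: covariates are projected out of both phenotype and dosage before
the single-variant fit, which is numerically identical (Frisch-Waugh-Lovell)
to including the covariates in a full regression. Scoring uses raw
effect-size sums over clumped hits (pruning + thresholding).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import qr
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score

from .synthetic import GenotypeMatrix

GENOME_WIDE_P = 5e-8
CLUMP_R2 = 0.1
LOCUS_MERGE_BP = 250_000


# ---------------------------------------------------------------------------
# association testing
# ---------------------------------------------------------------------------

@dataclass
class AssocResult:
    """Per-variant association statistics for one phenotype.

    ``table`` columns: CHR, POS, ID, BETA, SE, P, CODE (empty for tested
    variants, a skip code otherwise).
    """

    table: pd.DataFrame
    phenotype_id: str
    n_used: int

    def significant(self, p_threshold: float = GENOME_WIDE_P) -> pd.DataFrame:
        ok = self.table["CODE"] == ""
        return self.table[ok & (self.table["P"] <= p_threshold)]


def _design_matrix(covariates: pd.DataFrame | np.ndarray | None,
                   n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    return np.column_stack([np.ones(len(C)), C])


def standard_covariates(cov: pd.DataFrame) -> pd.DataFrame:
    """Expanded covariate set: age, sex, age^2, age*sex, height, height^2, bmi."""
    out = pd.DataFrame({
        "age": cov["age"], "sex": cov["sex"],
        "age2": cov["age"] ** 2, "age_sex": cov["age"] * cov["sex"],
        "height": cov["height"], "height2": cov["height"] ** 2,
        "bmi": cov["bmi"],
    })
    return out


def gwas(G: GenotypeMatrix, phenotype: np.ndarray,
         covariates: pd.DataFrame | np.ndarray | None = None,
         phenotype_id: str = "phenotype",
         min_n: int = 30) -> AssocResult:
    """Per-variant OLS with covariates projected out of phenotype and dosage.

    Rows with missing phenotype/covariate values are dropped (complete
    cases). Zero-variance variants are skipped with code ZERO_VARIANCE;
    a constant phenotype skips every variant with code CONSTANT_PHENOTYPE.
    """
    y = np.asarray(phenotype, dtype=float)
    n_all = G.n_individuals
    if y.shape != (n_all,):
        raise ValueError("phenotype length must match cohort size")
    C = _design_matrix(covariates, n_all)
    keep = np.isfinite(y) & np.all(np.isfinite(C), axis=1)
    if keep.sum() < min_n:
        raise ValueError(f"only {keep.sum()} complete cases; need >= {min_n}")
    y = y[keep]
    C = C[keep]
    D = G.dosages[keep]
    n = len(y)
    p_cov = C.shape[1]
    dof = n - p_cov - 1

    base = pd.DataFrame({
        "CHR": G.chromosome, "POS": G.position_bp, "ID": G.variant_ids,
    })

    if np.ptp(y) == 0:
        base["BETA"] = np.nan
        base["SE"] = np.nan
        base["P"] = np.nan
        base["CODE"] = "CONSTANT_PHENOTYPE"
        return AssocResult(table=base, phenotype_id=phenotype_id, n_used=n)

    # project covariates out of phenotype and dosages (FWL)
    Q, _ = np.linalg.qr(C)
    y_r = y - Q @ (Q.T @ y)
    X_r = D - Q @ (Q.T @ D)

    xx = np.einsum("ij,ij->j", X_r, X_r)
    xy = X_r.T @ y_r
    yy = float(y_r @ y_r)
    ok = xx > 1e-12
    beta = np.full(G.n_variants, np.nan)
    se = np.full(G.n_variants, np.nan)
    pval = np.full(G.n_variants, np.nan)
    beta[ok] = xy[ok] / xx[ok]
    rss = yy - beta[ok] ** 2 * xx[ok]
    rss = np.clip(rss, 0.0, None)
    sigma2 = rss / dof
    se[ok] = np.sqrt(sigma2 / xx[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta[ok] / se[ok]
    pv = 2 * stats.t.sf(np.abs(tstat), dof)
    pval[ok] = np.clip(pv, np.finfo(float).tiny, 1.0)

    base["BETA"] = beta
    base["SE"] = se
    base["P"] = pval
    base["CODE"] = np.where(ok, "", "ZERO_VARIANCE")
    return AssocResult(table=base, phenotype_id=phenotype_id, n_used=n)


def variant_qc_mask(G: GenotypeMatrix, maf_min: float = 0.001,
                    info: np.ndarray | None = None, info_min: float = 0.8,
                    max_missing: float = 0.05,
                    hwe_p_min: float = 1e-10) -> np.ndarray:
    """Configurable variant filters: MAF, INFO (defaults to 1 for hard
    calls), missingness, and a 1-df chi-square HWE test on rounded calls."""
    D = G.dosages
    miss = np.mean(~np.isfinite(D), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        af = np.nanmean(D, axis=0) / 2
    maf = np.minimum(af, 1 - af)
    keep = (maf >= maf_min) & (miss <= max_missing)
    if info is not None:
        keep &= np.asarray(info) >= info_min
    # HWE on hard calls
    calls = np.round(D)
    hwe_p = np.ones(G.n_variants)
    for j in np.where(keep)[0]:
        c = calls[np.isfinite(calls[:, j]), j]
        n0, n1, n2 = np.sum(c == 0), np.sum(c == 1), np.sum(c == 2)
        nt = n0 + n1 + n2
        if nt == 0:
            continue
        p = (2 * n2 + n1) / (2 * nt)
        exp = nt * np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
        obs = np.array([n0, n1, n2])
        mask = exp > 0
        chi2 = float(((obs[mask] - exp[mask]) ** 2 / exp[mask]).sum())
        hwe_p[j] = stats.chi2.sf(chi2, df=1)
    return keep & (hwe_p >= hwe_p_min)


def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform with the Blom offset
    (rank - 3/8) / (n + 1/4); ties get average rank."""
    x = np.asarray(values, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct values")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.375) / (x.size + 0.25))


# ---------------------------------------------------------------------------
# clumping and loci
# ---------------------------------------------------------------------------

class DosageLD:
    """Squared-correlation source computed from the cohort's own dosages
    (the analysis cohort doubles as the LD reference panel)."""

    def __init__(self, G: GenotypeMatrix):
        D = np.asarray(G.dosages, dtype=float)
        sd = D.std(axis=0)
        sd[sd == 0] = np.nan
        self._X = (D - D.mean(axis=0)) / sd
        self._n = D.shape[0]

    def r2_with(self, j: int) -> np.ndarray:
        """r^2 of variant ``j`` against every variant (NaN for constants)."""
        r = self._X.T @ self._X[:, j] / self._n
        return r ** 2


@dataclass
class Hit:
    variant_id: str
    chromosome: int
    position_bp: int
    p: float
    index: int  # column index into the genotype matrix


@dataclass
class Locus:
    chromosome: int
    start_bp: int
    end_bp: int
    lead_variant_id: str
    lead_p: float


def clump(assoc: AssocResult, ld: DosageLD,
          p_threshold: float = GENOME_WIDE_P,
          r2_threshold: float = CLUMP_R2) -> list[Hit]:
    """Greedy selection of independent significant variants.

    Repeatedly take the most significant remaining variant as a hit and
    remove all remaining significant variants with r^2 >= ``r2_threshold``
    to it. Ties on p broken by position, then id.
    """
    sig = assoc.significant(p_threshold).copy()
    if sig.empty:
        return []
    sig = sig.sort_values(["P", "POS", "ID"], kind="stable")
    remaining = list(sig.index)
    hits: list[Hit] = []
    while remaining:
        lead = remaining[0]
        row = assoc.table.loc[lead]
        hits.append(Hit(variant_id=row["ID"], chromosome=int(row["CHR"]),
                        position_bp=int(row["POS"]), p=float(row["P"]),
                        index=int(lead)))
        r2 = ld.r2_with(int(lead))
        remaining = [i for i in remaining[1:]
                     if not (r2[int(i)] >= r2_threshold)]
    return hits


def locus_spans(hits: list[Hit], G: GenotypeMatrix, ld: DosageLD,
                r2_threshold: float = CLUMP_R2) -> list[tuple[int, int]]:
    """Per-hit locus span: positions of all same-chromosome variants in LD
    (r^2 >= threshold) with the hit, including the hit itself."""
    spans = []
    for h in hits:
        r2 = ld.r2_with(h.index)
        partners = np.where((r2 >= r2_threshold)
                            & (G.chromosome == h.chromosome))[0]
        if partners.size:
            pos = G.position_bp[partners]
            spans.append((int(pos.min()), int(pos.max())))
        else:
            spans.append((h.position_bp, h.position_bp))
    return spans


def merge_loci(hits: list[Hit],
               spans: list[tuple[int, int]] | None = None,
               merge_distance: int = LOCUS_MERGE_BP) -> list[Locus]:
    """Merge per-hit spans on the same chromosome whose gap is smaller than
    ``merge_distance``; the merged locus lead is its smallest-p hit.
    Idempotent."""
    if not hits:
        return []
    if spans is None:
        spans = [(h.position_bp, h.position_bp) for h in hits]
    items = sorted(zip(hits, spans),
                   key=lambda hs: (hs[0].chromosome, hs[1][0], hs[1][1]))
    loci: list[Locus] = []
    cur_hits = [items[0][0]]
    cur_start, cur_end = items[0][1]
    cur_chrom = items[0][0].chromosome

    def close(hl, chrom, start, end):
        lead = min(hl, key=lambda h: (h.p, h.position_bp, h.variant_id))
        loci.append(Locus(chromosome=chrom, start_bp=start, end_bp=end,
                          lead_variant_id=lead.variant_id, lead_p=lead.p))

    for h, (s, e) in items[1:]:
        if h.chromosome == cur_chrom and s - cur_end < merge_distance:
            cur_end = max(cur_end, e)
            cur_hits.append(h)
        else:
            close(cur_hits, cur_chrom, cur_start, cur_end)
            cur_hits, cur_chrom, cur_start, cur_end = [h], h.chromosome, s, e
    close(cur_hits, cur_chrom, cur_start, cur_end)
    return loci


# ---------------------------------------------------------------------------
# polygenic scoring
# ---------------------------------------------------------------------------

def score_prs(G: GenotypeMatrix, betas: pd.Series | dict) -> np.ndarray:
    """score_i = sum_j dosage_ij * beta_j over variants matched by id."""
    if isinstance(betas, dict):
        betas = pd.Series(betas)
    id_to_col = {vid: j for j, vid in enumerate(G.variant_ids)}
    matched = [vid for vid in betas.index if vid in id_to_col]
    missing = len(betas) - len(matched)
    if not matched:
        raise ValueError("no scoring variants matched the genotype matrix")
    if missing:
        warnings.warn(f"{missing} scoring variants not in genotype matrix",
                      stacklevel=2)
    cols = [id_to_col[v] for v in matched]
    return G.dosages[:, cols] @ betas.loc[matched].to_numpy(dtype=float)


def prs_from_assoc(G: GenotypeMatrix, assoc: AssocResult, ld: DosageLD,
                   p_threshold: float = GENOME_WIDE_P,
                   r2_threshold: float = CLUMP_R2) -> np.ndarray:
    """Pruning+thresholding PRS: clump, then score with the hits' raw betas."""
    hits = clump(assoc, ld, p_threshold, r2_threshold)
    if not hits:
        return np.zeros(G.n_individuals)
    betas = pd.Series({h.variant_id:
                       float(assoc.table.loc[h.index, "BETA"]) for h in hits})
    return score_prs(G, betas)


@dataclass
class PRSProfile:
    """One intermediate PRS column per encoding coordinate / EDF."""

    scores: pd.DataFrame  # (n_individuals, n_columns)
    source_ids: list[str] = field(default_factory=list)

    @property
    def matrix(self) -> np.ndarray:
        return self.scores.to_numpy(dtype=float)


def build_prs_profile(G_train: GenotypeMatrix, phenotypes: pd.DataFrame,
                      covariates: pd.DataFrame | None,
                      G_score: GenotypeMatrix | None = None,
                      p_threshold: float = GENOME_WIDE_P,
                      r2_threshold: float = CLUMP_R2) -> PRSProfile:
    """GWAS each phenotype column on the training cohort, clump, and score
    (on ``G_score`` if given, else the training cohort)."""
    Gs = G_score if G_score is not None else G_train
    ld = DosageLD(G_train)
    cols = {}
    for name in phenotypes.columns:
        res = gwas(G_train, phenotypes[name].to_numpy(), covariates,
                   phenotype_id=str(name))
        hits = clump(res, ld, p_threshold, r2_threshold)
        if hits:
            betas = pd.Series({h.variant_id:
                               float(res.table.loc[h.index, "BETA"])
                               for h in hits})
            cols[name] = score_prs(Gs, betas)
        else:
            cols[name] = np.zeros(Gs.n_individuals)
    return PRSProfile(scores=pd.DataFrame(cols),
                      source_ids=list(phenotypes.columns))


# ---------------------------------------------------------------------------
# combination and evaluation
# ---------------------------------------------------------------------------

@dataclass
class CombinedPRS:
    weights: np.ndarray
    intercept: float
    scores: np.ndarray
    trait_id: str
    family: str
    column_names: list[str]
    ridge_fallback: bool = False

    def apply(self, profile: PRSProfile) -> np.ndarray:
        return self.intercept + profile.scores[self.column_names].to_numpy(
            dtype=float) @ self.weights


def combine_prs(profile: PRSProfile, labels: np.ndarray,
                family: str = "logistic",
                trait_id: str = "trait",
                min_n: int = 50) -> CombinedPRS:
    """Learn the linear mixture of intermediate PRSs from labels.

    Binary labels: maximum-likelihood logistic regression (falling back to
    a ridge-penalized fit on perfect separation, flagged). Continuous
    labels (family='linear'): ordinary least squares.
    """
    X = profile.matrix
    y = np.asarray(labels, dtype=float)
    if len(y) != len(X):
        raise ValueError("labels must align with the PRS profile")
    if len(y) < min_n:
        raise ValueError(f"need >= {min_n} labeled individuals, got {len(y)}")
    fallback = False
    if family == "logistic":
        if np.unique(y).size < 2:
            raise ValueError("need at least 1 case and 1 control")
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                model = LogisticRegression(C=np.inf, max_iter=2000)
                model.fit(X, y)
                prob = model.predict_proba(X)[:, 1]
                # a perfectly classifying fit means the data are separated,
                # so the unpenalized MLE diverges
                if np.all((prob > 0.5) == (y == 1)):
                    raise ConvergenceWarning("separation detected")
            except ConvergenceWarning:
                fallback = True
                model = LogisticRegression(C=1.0, max_iter=2000)
                model.fit(X, y)
        w = model.coef_.ravel()
        b = float(model.intercept_[0])
    elif family == "linear":
        model = LinearRegression()
        model.fit(X, y)
        w = model.coef_.ravel()
        b = float(model.intercept_)
    else:
        raise ValueError(f"unknown family {family!r}")
    return CombinedPRS(weights=w, intercept=b, scores=b + X @ w,
                       trait_id=trait_id, family=family,
                       column_names=list(profile.scores.columns),
                       ridge_fallback=fallback)


def _stratum_prevalence(scores: np.ndarray, labels: np.ndarray,
                        frac: float, top: bool) -> float:
    n = len(scores)
    k = max(1, int(round(frac * n)))
    order = np.argsort(-scores if top else scores, kind="stable")
    return float(labels[order[:k]].mean())


def evaluate_prs(scores: np.ndarray, labels: np.ndarray,
                 percentiles: tuple[int, ...] = (5, 10, 20)) -> dict:
    """AUC-ROC, AUC-PR, Pearson/Spearman correlation, and case prevalence
    in the top/bottom score strata. Strata are rank-based (equivalent to
    interpolated quantile thresholds for distinct scores; ties broken by
    stable individual order)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    out: dict[str, float] = {}
    binary = set(np.unique(y)) <= {0.0, 1.0}
    if binary and np.unique(y).size == 2:
        out["auc_roc"] = float(roc_auc_score(y, s))
        out["auc_pr"] = float(average_precision_score(y, s))
        for k in percentiles:
            out[f"top{k}_prevalence"] = _stratum_prevalence(s, y, k / 100, True)
            out[f"bottom{k}_prevalence"] = _stratum_prevalence(s, y, k / 100,
                                                               False)
        out["overall_prevalence"] = float(y.mean())
    elif binary:
        out["auc_roc"] = np.nan
        out["auc_pr"] = np.nan
        out["flag"] = "single-class labels: AUC undefined"
    if np.ptp(s) > 0 and np.ptp(y) > 0:
        out["pearson"] = float(stats.pearsonr(s, y).statistic)
        out["spearman"] = float(stats.spearmanr(s, y).statistic)
    else:
        out["pearson"] = np.nan
        out["spearman"] = np.nan
    return out


@dataclass
class BootstrapComparison:
    difference: float
    ci_low: float
    ci_high: float
    significant: bool
    metric: str
    reps: int


def paired_bootstrap_compare(scores_a: np.ndarray, scores_b: np.ndarray,
                             labels: np.ndarray, metric: str = "auc_roc",
                             reps: int = 300, level: float = 0.95,
                             seed: int = 0) -> BootstrapComparison:
    """Percentile CI of metric(a) - metric(b) over paired resamples of
    individuals; significant iff the CI excludes 0."""
    if reps < 50:
        warnings.warn(f"reps={reps} < 50: CI will be unstable", stacklevel=2)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=float)
    if not (len(a) == len(b) == len(y)):
        raise ValueError("scores and labels must align")

    def m(s, yy):
        return evaluate_prs(s, yy)[metric]

    point = m(a, y) - m(b, y)
    rng = np.random.default_rng(seed)
    diffs = []
    for _ in range(reps):
        idx = rng.integers(0, len(y), size=len(y))
        yy = y[idx]
        if np.unique(yy).size < 2 and metric in ("auc_roc", "auc_pr"):
            continue
        diffs.append(m(a[idx], yy) - m(b[idx], yy))
    diffs = np.asarray(diffs)
    alpha = (1 - level) / 2
    lo, hi = np.percentile(diffs, [100 * alpha, 100 * (1 - alpha)])
    return BootstrapComparison(difference=float(point), ci_low=float(lo),
                               ci_high=float(hi),
                               significant=bool(lo > 0 or hi < 0),
                               metric=metric, reps=reps)


# ---------------------------------------------------------------------------
# residualization
# ---------------------------------------------------------------------------

def residualize(encodings: np.ndarray,
                features: np.ndarray | pd.DataFrame) -> np.ndarray:
    """OLS residuals of each encoding coordinate on the features
    (with intercept). Collinear feature columns are dropped (logged)."""
    E = np.asarray(encodings, dtype=float)
    if E.ndim == 1:
        E = E[:, None]
    F = np.asarray(features, dtype=float)
    if F.ndim == 1:
        F = F[:, None]
    if not (np.all(np.isfinite(E)) and np.all(np.isfinite(F))):
        raise ValueError("complete cases required")
    X = np.column_stack([np.ones(len(F)), F])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, piv = qr(X, pivoting=True)
        keep = np.sort(piv[:rank])
        warnings.warn(f"dropping {X.shape[1] - rank} collinear feature "
                      "column(s)", stacklevel=2)
        X = X[:, keep]
    coef, *_ = np.linalg.lstsq(X, E, rcond=None)
    return E - X @ coef
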