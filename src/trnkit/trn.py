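"""Prior-constrained LASSO inference of a transcriptional regulatory network.

Each gene's (normalized) expression is regressed on the expression of the TFs
that have a binding-site prior for that gene, with L1 regularization pruning
weak candidates.  A single penalty is used for every gene, chosen by the
one-standard-error rule in cross-validation on a random subset of probe genes
and taking the median across probes.  Genes are kept in the final network
when the model explains more than half of their expression variance in a
training split; kept genes are refit on all samples to produce the final
signed TF -> gene edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx

from .lasso import lambda_max, lasso_fit, lasso_path
from .nbglm import size_factors
from .priors import PriorMatrix

__all__ = [
    "ExpressionMatrix",
    "GeneFit",
    "TRNModel",
    "TFModule",
    "preprocess_expression",
    "fit_gene",
    "select_penalty",
    "fit_network",
    "extract_modules",
    "extract_tf_tf_subnetwork",
    "tf_subnetwork_graph",
]


@dataclass
class ExpressionMatrix:
    """Normalized expression: genes x samples, z-scored per gene.

    ``log_normalized`` holds the pre-z-score log2 CPM values (used e.g. for
    the expressed-TF rule); ``values`` is the z-scored matrix used for
    modeling.  ``design`` optionally carries per-sample covariates
    (allele, age, sex) used for stratified splitting.
    """

    values: pd.DataFrame
    log_normalized: pd.DataFrame
    design: pd.DataFrame | None = None
    from_counts: bool = True
    excluded_genes: tuple[str, ...] = ()

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)


@dataclass
class GeneFit:
    gene: str
    selected_tfs: list[str]
    coefficients: dict[str, float]
    intercept: float
    r2_train: float
    r2_cv: float
    kept: bool


@dataclass
class TRNModel:
    """Fitted network: signed weighted TF -> gene edges plus per-gene fits."""

    edges: pd.DataFrame          # columns: tf, gene, weight
    fits: pd.DataFrame           # columns: gene, n_prior_tfs, r2_train, r2_cv, kept
    penalty: float
    accuracy_correlation: float  # Pearson r of r2_train vs r2_cv across genes
    metadata: dict = field(default_factory=dict)

    @property
    def kept_genes(self) -> list[str]:
        return list(self.fits.loc[self.fits["kept"], "gene"])

    @property
    def tfs(self) -> list[str]:
        return sorted(self.edges["tf"].unique())

    def summary(self) -> dict:
        tfs_per_gene = self.edges.groupby("gene").size()
        targets_per_tf = self.edges.groupby("tf").size()
        return {
            "n_kept_genes": len(self.kept_genes),
            "n_edges": len(self.edges),
            "n_tfs": len(targets_per_tf),
            "median_tfs_per_gene": float(tfs_per_gene.median()) if len(tfs_per_gene) else 0.0,
            "median_targets_per_tf": float(targets_per_tf.median()) if len(targets_per_tf) else 0.0,
            "accuracy_correlation": self.accuracy_correlation,
        }


@dataclass
class TFModule:
    """A TF and the genes it is predicted to regulate directly."""

    tf: str
    targets: tuple[str, ...]
    weights: dict[str, float]

    def __len__(self):
        return len(self.targets)


def _sq_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def preprocess_expression(
    counts: pd.DataFrame,
    design: pd.DataFrame | None = None,
    tf_list: list[str] | None = None,
    *,
    expression_floor: float = 1.0,
    min_expressed_fraction: float = 0.5,
    already_normalized: bool = False,
) -> tuple[ExpressionMatrix, list[str]]:
    """Counts -> CPM -> log2(x+1) -> per-gene z-score; select expressed TFs.

    A TF is retained as a potential regulator when its log2-CPM is at or
    above ``expression_floor`` in at least ``min_expressed_fraction`` of
    samples.  All-zero or constant genes are excluded from modeling and
    listed in ``excluded_genes``.  With ``already_normalized`` the CPM/log
    steps are skipped and the input is only z-scored.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    if already_normalized:
        logn = counts.astype(float)
    else:
        # median-of-ratios size factors (robust to asymmetric expression
        # shifts), scaled so values are on the familiar counts-per-million
        # scale of an average library
        sf = size_factors(counts.to_numpy())
        eff_lib = sf * counts.sum(axis=0).mean()
        cpm = counts / eff_lib * 1e6
        logn = np.log2(cpm + 1.0)
    sd = logn.std(axis=1, ddof=0)
    excluded = tuple(logn.index[sd == 0])
    modeled = logn.loc[sd > 0]
    z = modeled.sub(modeled.mean(axis=1), axis=0).div(
        modeled.std(axis=1, ddof=0), axis=0
    )
    expressed_tfs: list[str] = []
    if tf_list is not None:
        for tf in tf_list:
            if tf not in logn.index or tf in excluded:
                continue
            frac = float((logn.loc[tf] >= expression_floor).mean())
            if frac >= min_expressed_fraction:
                expressed_tfs.append(tf)
    expr = ExpressionMatrix(
        values=z,
        log_normalized=logn,
        design=design,
        from_counts=not already_normalized,
        excluded_genes=excluded,
    )
    return expr, expressed_tfs


def fit_gene(
    y: np.ndarray,
    X: np.ndarray,
    lam: float,
    tf_names: list[str],
    gene: str = "",
    keep_threshold: float = 0.5,
) -> GeneFit:
    """Fit one gene's prior-constrained lasso at a fixed penalty.

    The candidate matrix ``X`` must already exclude the gene itself.  With an
    empty candidate set the fit is intercept-only with r^2 = 0 and the gene
    is not kept.
    """
    y = np.asarray(y, dtype=float)
    if X.size == 0 or X.shape[1] == 0:
        return GeneFit(gene, [], {}, float(np.mean(y)), 0.0, 0.0, False)
    if len(y) < 10:
        raise ValueError("need at least 10 samples to fit a gene model")
    intercept, beta = lasso_fit(X, y, lam)
    pred = intercept + X @ beta
    r2 = _sq_pearson(pred, y)
    nz = np.flatnonzero(beta)
    return GeneFit(
        gene=gene,
        selected_tfs=[tf_names[j] for j in nz],
        coefficients={tf_names[j]: float(beta[j]) for j in nz},
        intercept=float(intercept),
        r2_train=r2,
        r2_cv=np.nan,
        kept=bool(r2 > keep_threshold),
    )


def _modelable_genes(expr: ExpressionMatrix, prior: PriorMatrix) -> list[str]:
    tf_rows = set(expr.values.index)
    out = []
    for gene in expr.values.index:
        tfs = [t for t in prior.tfs_for_gene(gene) if t in tf_rows and t != gene]
        if tfs:
            out.append(gene)
    return out


def _design_matrix(expr, prior, gene):
    tf_rows = set(expr.values.index)
    tfs = [t for t in prior.tfs_for_gene(gene) if t in tf_rows and t != gene]
    X = expr.values.loc[tfs].to_numpy().T if tfs else np.zeros((len(expr.samples), 0))
    y = expr.values.loc[gene].to_numpy()
    return y, X, tfs


def _lambda_grid(lmax: float, n_lambda: int, min_ratio: float) -> np.ndarray:
    lmax = max(lmax, 1e-12)
    return np.geomspace(lmax, lmax * min_ratio, n_lambda)


def select_penalty(
    expr: ExpressionMatrix,
    prior: PriorMatrix,
    n_probe_genes: int = 100,
    folds: int = 5,
    seed: int = 0,
    *,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-3,
    full_output: bool = False,
):
    """Choose the uniform penalty by the 1-SE rule on random probe genes.

    For each probe gene, fold-averaged CV mean squared error is computed over
    a log-spaced penalty grid descending from that gene's lambda_max; the
    largest penalty whose CV error is within one standard error (SD of fold
    errors / sqrt(folds)) of the minimum is picked.  Returns the lower median
    of the per-gene picks (with ``full_output``, a tuple of the median, the
    per-probe picks and the probe gene list).  Fully determined by ``seed``.
    """
    rng = np.random.default_rng(seed)
    genes = _modelable_genes(expr, prior)
    if len(genes) < n_probe_genes:
        warnings.warn(
            f"only {len(genes)} modelable genes; using all as probes", stacklevel=2
        )
        probes = list(genes)
    else:
        probes = list(rng.choice(genes, size=n_probe_genes, replace=False))
    n = len(expr.samples)
    if n < folds:
        raise ValueError("fewer samples than folds")
    picks = []
    for gene in probes:
        y, X, _ = _design_matrix(expr, prior, gene)
        lmax = lambda_max(X, y)
        grid = _lambda_grid(lmax, n_lambda, lambda_min_ratio)
        fold_ids = rng.permutation(np.arange(n) % folds)
        errs = np.zeros((folds, n_lambda))
        for f in range(folds):
            test = fold_ids == f
            inters, betas = lasso_path(X[~test], y[~test], grid)
            preds = X[test] @ betas.T + inters[None, :]
            errs[f] = ((preds - y[test][:, None]) ** 2).mean(axis=0)
        cvm = errs.mean(axis=0)
        if np.allclose(cvm, cvm[0]):
            warnings.warn("degenerate CV curve; taking largest penalty", stacklevel=2)
            picks.append(grid[0])
            continue
        i_min = int(np.argmin(cvm))
        se = float(errs[:, i_min].std(ddof=1) / np.sqrt(folds))
        # grid is descending, so the first index satisfying the rule is the
        # largest (most stringent) penalty
        i_pick = int(np.flatnonzero(cvm <= cvm[i_min] + se)[0])
        picks.append(grid[i_pick])
    picks = np.asarray(picks)
    median = float(np.sort(picks)[(len(picks) - 1) // 2])  # lower median
    if full_output:
        return median, picks, probes
    return median


def _stratified_split(expr, split_fraction, rng):
    n = len(expr.samples)
    train = np.zeros(n, dtype=bool)
    if expr.design is not None and {"allele", "age"} <= set(expr.design.columns):
        strata = expr.design.loc[expr.samples, ["allele", "age"]].astype(str).agg(
            "|".join, axis=1
        )
        for _, idx in pd.Series(np.arange(n), index=strata.values).groupby(level=0):
            members = idx.to_numpy()
            k = max(1, round(split_fraction * len(members)))
            train[rng.permutation(members)[:k]] = True
    else:
        k = max(1, round(split_fraction * n))
        train[rng.permutation(n)[:k]] = True
    return train


def fit_network(
    expr: ExpressionMatrix,
    prior: PriorMatrix,
    penalty: float,
    split_fraction: float = 0.8,
    keep_threshold: float = 0.5,
    folds: int = 5,
    seed: int = 0,
) -> TRNModel:
    """Fit the full prior-constrained network at a fixed uniform penalty.

    Per gene: fit on a training split (stratified by allele x age when a
    design is attached); r2_train is the squared Pearson correlation of
    predicted vs observed expression on the training samples and r2_cv the
    same on out-of-fold predictions from ``folds``-fold CV over all samples.
    Genes with r2_train > ``keep_threshold`` are refit on all samples; their
    nonzero coefficients become the network edges.
    """
    if penalty <= 0:
        raise ValueError("penalty must be positive")
    n = len(expr.samples)
    if n < folds:
        raise ValueError("fewer samples than folds")
    rng = np.random.default_rng(seed)
    train = _stratified_split(expr, split_fraction, rng)
    fold_ids = rng.permutation(np.arange(n) % folds)

    genes = _modelable_genes(expr, prior)
    fit_rows = []
    edge_rows = []
    for gene in genes:
        y, X, tfs = _design_matrix(expr, prior, gene)
        inter_t, beta_t = lasso_fit(X[train], y[train], penalty)
        pred_t = inter_t + X[train] @ beta_t
        r2_train = _sq_pearson(pred_t, y[train])
        oof = np.zeros(n)
        for f in range(folds):
            test = fold_ids == f
            inter_f, beta_f = lasso_fit(X[~test], y[~test], penalty)
            oof[test] = inter_f + X[test] @ beta_f
        r2_cv = _sq_pearson(oof, y)
        kept = bool(r2_train > keep_threshold)
        fit_rows.append((gene, len(tfs), r2_train, r2_cv, kept))
        if kept:
            _, beta_full = lasso_fit(X, y, penalty)
            for j in np.flatnonzero(beta_full):
                edge_rows.append((tfs[j], gene, float(beta_full[j])))

    fits = pd.DataFrame(
        fit_rows, columns=["gene", "n_prior_tfs", "r2_train", "r2_cv", "kept"]
    )
    edges = pd.DataFrame(edge_rows, columns=["tf", "gene", "weight"])
    if len(fits) > 1 and fits["r2_train"].std() > 0 and fits["r2_cv"].std() > 0:
        acc_r = float(np.corrcoef(fits["r2_train"], fits["r2_cv"])[0, 1])
    else:
        acc_r = np.nan
    return TRNModel(
        edges=edges,
        fits=fits,
        penalty=float(penalty),
        accuracy_correlation=acc_r,
        metadata={
            "seed": seed,
            "split_fraction": split_fraction,
            "keep_threshold": keep_threshold,
            "folds": folds,
            "n_samples": n,
        },
    )


def extract_modules(model: TRNModel, min_targets: int = 10) -> dict[str, TFModule]:
    """TF-target modules: per TF, its predicted direct targets (signed)."""
    modules = {}
    for tf, grp in model.edges.groupby("tf"):
        if len(grp) < min_targets:
            continue
        modules[tf] = TFModule(
            tf=tf,
            targets=tuple(grp["gene"]),
            weights=dict(zip(grp["gene"], grp["weight"])),
        )
    return modules


def extract_tf_tf_subnetwork(model: TRNModel, tf_set: set[str]) -> pd.DataFrame:
    """Direct regulatory edges among a set of TFs.

    Returns edges (tf -> target TF) where the target TF appears as a target
    gene in the model and both ends are in ``tf_set``; ``sign`` is the
    coefficient sign and ``width`` its magnitude (for plotting).
    """
    tf_set = set(tf_set)
    sub = model.edges[
        model.edges["tf"].isin(tf_set) & model.edges["gene"].isin(tf_set)
    ].copy()
    sub["sign"] = np.sign(sub["weight"]).astype(int)
    sub["width"] = sub["weight"].abs()
    return sub.reset_index(drop=True)


def tf_subnetwork_graph(model: TRNModel, tf_set: set[str]) -> nx.DiGraph:
    """The TF-TF subnetwork as a directed graph with sign/weight attributes."""
    sub = extract_tf_tf_subnetwork(model, tf_set)
    g = nx.DiGraph()
    g.add_nodes_from(sorted(tf_set))
    for row in sub.itertuples():
        g.add_edge(row.tf, row.gene, weight=row.weight, sign=row.sign, width=row.width)
    return g
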