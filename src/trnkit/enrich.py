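"""Condition-specific module enrichment and core-TF identification.

The study design is an allelic series: mouse lines carrying Htt CAG-repeat
knock-in alleles of increasing length (reference Q20 up to Q175), profiled at
several ages.  Each (pathogenic allele, age) pair defines a condition whose
differentially expressed genes (up and down separately) are tested for
over-representation in every TF-target module by one-sided Fisher exact
tests.  A TF is called a *core* regulator when its module is enriched
(raw P < 1e-6) in at least five of the fifteen conditions; an empirical FDR
for that call is obtained by rerunning the entire DE + enrichment pipeline on
label-permuted data.  Replication across independent studies is combined by
Fisher's method.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .nbglm import nb_lrt_two_group
from .trn import TFModule

__all__ = [
    "Condition",
    "EnrichmentResult",
    "MetaResult",
    "PermutationNull",
    "conditions_from_design",
    "differential_expression",
    "ingest_de_table",
    "call_degs",
    "fisher_enrichment",
    "module_condition_enrichment",
    "core_tf_selection",
    "permutation_fdr",
    "fisher_method_meta",
    "correlation_enrichment",
    "overlap_test",
    "geneset_enrichment",
    "signed_logp_matrix",
]


@dataclass(frozen=True)
class Condition:
    """A case-vs-reference contrast at one age."""

    case_allele: str
    ref_allele: str
    age: float

    def __post_init__(self):
        if self.case_allele == self.ref_allele:
            raise ValueError("case and reference alleles must differ")

    @property
    def label(self) -> str:
        return f"{self.case_allele}@{self.age:g}mo"


@dataclass
class EnrichmentResult:
    """One module x DEG-set Fisher test: 2x2 counts, OR, one-sided P."""

    module: str
    condition: str
    direction: str
    a: int  # module & DEG
    b: int  # module & not DEG
    c: int  # DEG & not module
    d: int  # neither
    odds_ratio: float
    odds_ratio_display: float  # Haldane 0.5-corrected when a cell is zero
    p: float


@dataclass
class MetaResult:
    """Fisher's-method combination of independent study P-values."""

    pvalues: tuple[float, ...]
    chi2: float
    df: int
    combined_p: float


def conditions_from_design(
    design: pd.DataFrame, ref_allele: str = "Q20"
) -> list[Condition]:
    """All case-allele x age contrasts against the reference allele."""
    alleles = [a for a in design["allele"].unique() if a != ref_allele]
    ages = sorted(design["age"].unique())
    return [Condition(a, ref_allele, age) for a in alleles for age in ages]


def _condition_samples(design: pd.DataFrame, condition: Condition):
    at_age = design[design["age"] == condition.age]
    case = at_age.index[at_age["allele"] == condition.case_allele]
    ref = at_age.index[at_age["allele"] == condition.ref_allele]
    return list(case), list(ref)


def differential_expression(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    condition: Condition,
    *,
    case_samples: list[str] | None = None,
    ref_samples: list[str] | None = None,
) -> pd.DataFrame:
    """Two-group NB likelihood-ratio test for one condition.

    Returns a frame indexed by gene with ``log2_fc`` (case vs reference),
    ``pvalue`` and ``direction`` ('up'/'down' by fold-change sign).  Genes
    with all-zero counts across the tested samples are dropped.  Explicit
    sample lists override the design lookup (used by the permutation null).
    """
    if case_samples is None or ref_samples is None:
        case_samples, ref_samples = _condition_samples(design, condition)
    if len(case_samples) < 2 or len(ref_samples) < 2:
        raise ValueError(
            f"condition {condition.label}: each group needs >= 2 samples"
        )
    sub = counts[list(case_samples) + list(ref_samples)]
    nonzero = sub.sum(axis=1) > 0
    sub = sub.loc[nonzero]
    is_case = np.array([True] * len(case_samples) + [False] * len(ref_samples))
    res = nb_lrt_two_group(sub.to_numpy(), is_case)
    out = pd.DataFrame(
        {
            "log2_fc": res["log2_fc"],
            "pvalue": res["pvalue"],
        },
        index=sub.index,
    )
    out["direction"] = np.where(out["log2_fc"] > 0, "up", "down")
    out.loc[out["log2_fc"] == 0, "direction"] = "none"
    return out


def ingest_de_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate an externally computed DE table (e.g. edgeR/limma output).

    Expects columns ``gene``, ``log2_fc``, ``pvalue`` (extra columns kept);
    returns the standard frame indexed by gene with a ``direction`` column.
    """
    missing = {"gene", "log2_fc", "pvalue"} - set(table.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    out = table.set_index("gene").copy()
    if ((out["pvalue"] <= 0) | (out["pvalue"] > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    out["direction"] = np.where(out["log2_fc"] > 0, "up", "down")
    out.loc[out["log2_fc"] == 0, "direction"] = "none"
    return out


def call_degs(de: pd.DataFrame, p_threshold: float = 0.01):
    """Split significant genes by direction (strict P < threshold).

    Genes with exactly zero fold change are excluded from both sets.
    """
    sig = de[(de["pvalue"] < p_threshold) & (de["log2_fc"] != 0)]
    up = set(sig.index[sig["log2_fc"] > 0])
    down = set(sig.index[sig["log2_fc"] < 0])
    return up, down


def _fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher exact P: hypergeometric upper tail."""
    n_univ = a + b + c + d
    return float(stats.hypergeom.sf(a - 1, n_univ, a + c, a + b))


def _odds_ratios(a, b, c, d):
    raw = np.inf if b * c == 0 and a * d > 0 else ((a * d) / (b * c) if b * c else 0.0)
    if min(a, b, c, d) == 0:
        disp = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        disp = raw
    return raw, disp


def fisher_enrichment(
    module: TFModule | set[str],
    deg_set: set[str],
    universe: set[str],
    *,
    module_id: str = "",
    condition: str = "",
    direction: str = "",
) -> EnrichmentResult:
    """One-sided Fisher test of a module against a DEG set.

    Sets outside the universe are intersected away (with a warning); an empty
    module after intersection is an error.  The P-value is the exact
    hypergeometric upper tail; the odds ratio is reported raw, with a
    Haldane 0.5 display correction when a cell is zero (P never corrected).
    """
    if isinstance(module, TFModule):
        module_id = module_id or module.tf
        targets = set(module.targets)
    else:
        targets = set(module)
    universe = set(universe)
    if not targets <= universe:
        warnings.warn("module extends beyond universe; intersecting", stacklevel=2)
    if not deg_set <= universe:
        warnings.warn("DEG set extends beyond universe; intersecting", stacklevel=2)
    targets &= universe
    degs = set(deg_set) & universe
    if not targets:
        raise ValueError(f"module {module_id!r} empty after universe intersection")
    a = len(targets & degs)
    b = len(targets) - a
    c = len(degs) - a
    d = len(universe) - a - b - c
    raw, disp = _odds_ratios(a, b, c, d)
    return EnrichmentResult(
        module=module_id, condition=condition, direction=direction,
        a=a, b=b, c=c, d=d,
        odds_ratio=raw, odds_ratio_display=disp,
        p=_fisher_one_sided(a, b, c, d),
    )


def _vectorized_enrichment(membership: np.ndarray, deg_mask: np.ndarray) -> np.ndarray:
    """One-sided Fisher P per module; membership (modules x universe) bool."""
    n_univ = membership.shape[1]
    m_sizes = membership.sum(axis=1)
    k = int(deg_mask.sum())
    a = membership @ deg_mask
    return stats.hypergeom.sf(a - 1, n_univ, k, m_sizes)


def module_condition_enrichment(
    modules: dict[str, TFModule],
    de_results: dict[str, pd.DataFrame],
    universe: set[str],
    p_threshold: float = 0.01,
) -> pd.DataFrame:
    """Long table of module x condition x direction enrichment tests."""
    rows = []
    for cond_label, de in de_results.items():
        up, down = call_degs(de, p_threshold)
        for direction, degs in (("up", up), ("down", down)):
            for tf, module in modules.items():
                res = fisher_enrichment(
                    module, degs, universe,
                    module_id=tf, condition=cond_label, direction=direction,
                )
                rows.append(res.__dict__)
    return pd.DataFrame(rows)


def core_tf_selection(
    enrichment: pd.DataFrame,
    sig_threshold: float = 1e-6,
    min_conditions: int = 5,
    n_tests: int | None = None,
    bonferroni_threshold: float = 0.02,
) -> pd.DataFrame:
    """Tally significant conditions per module and flag core TFs.

    Per condition the better (minimum) of the up/down P-values is used; a
    condition counts when that P is strictly below ``sig_threshold``; the
    core flag requires at least ``min_conditions`` such conditions.  A
    Bonferroni view (min P x total tests vs 0.02) is reported alongside.
    """
    min_p = (
        enrichment.groupby(["module", "condition"])["p"].min().reset_index()
    )
    if n_tests is None:
        n_tests = enrichment[["module", "condition", "direction"]].drop_duplicates().shape[0]
    rows = []
    for module, grp in min_p.groupby("module"):
        n_sig = int((grp["p"] < sig_threshold).sum())
        best = float(grp["p"].min())
        rows.append(
            dict(
                module=module,
                n_sig_conditions=n_sig,
                core=n_sig >= min_conditions,
                min_p=best,
                bonferroni_sig=bool(min(best * n_tests, 1.0) < bonferroni_threshold),
            )
        )
    return pd.DataFrame(rows).sort_values(
        ["n_sig_conditions", "min_p"], ascending=[False, True]
    ).reset_index(drop=True)


@dataclass
class PermutationNull:
    """Null distribution of per-module significant-condition counts."""

    counts: pd.DataFrame        # permutations x modules
    sig_threshold: float
    min_conditions: int
    seed: int
    max_per_permutation: np.ndarray = field(init=False)

    def __post_init__(self):
        self.max_per_permutation = self.counts.to_numpy().max(axis=1)

    def n_null_core(self) -> int:
        """Total module x permutation instances reaching the core rule."""
        return int((self.counts.to_numpy() >= self.min_conditions).sum())

    def empirical_fdr(self, n_observed_core: int) -> float:
        """Expected null core calls per permutation over observed core calls."""
        if n_observed_core == 0:
            return float("nan")
        expected = self.n_null_core() / len(self.counts)
        return min(1.0, expected / n_observed_core)


def permutation_fdr(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    modules: dict[str, TFModule],
    B: int = 1000,
    seed: int = 0,
    *,
    conditions: list[Condition] | None = None,
    universe: set[str] | None = None,
    p_threshold: float = 0.01,
    sig_threshold: float = 1e-6,
    min_conditions: int = 5,
    ref_allele: str = "Q20",
) -> PermutationNull:
    """Empirical null for the core-TF rule by sample-label permutation.

    For each permutation, case/reference labels are shuffled within each
    condition's sample pool (group sizes preserved) and the full DE +
    enrichment pipeline is recomputed; per module, the number of conditions
    with min-direction P below ``sig_threshold`` is recorded.
    """
    if B < 1:
        raise ValueError("need at least one permutation")
    if conditions is None:
        conditions = conditions_from_design(design, ref_allele)
    if universe is None:
        universe = set(counts.index)
    rng = np.random.default_rng(seed)
    universe_list = sorted(universe)
    uidx = {g: i for i, g in enumerate(universe_list)}
    module_names = sorted(modules)
    membership = np.zeros((len(module_names), len(universe_list)), dtype=bool)
    for mi, name in enumerate(module_names):
        for g in modules[name].targets:
            if g in uidx:
                membership[mi, uidx[g]] = True
    if not membership.any(axis=1).all():
        raise ValueError("some modules are empty after universe intersection")

    pools = []
    for cond in conditions:
        case, ref = _condition_samples(design, cond)
        pools.append((cond, case, ref))

    null_counts = np.zeros((B, len(module_names)), dtype=int)
    for b in range(B):
        min_p = np.ones((len(module_names), len(conditions)))
        for ci, (cond, case, ref) in enumerate(pools):
            pool = np.array(list(case) + list(ref))
            perm = rng.permutation(len(pool))
            new_case = list(pool[perm[: len(case)]])
            new_ref = list(pool[perm[len(case):]])
            de = differential_expression(
                counts, design, cond, case_samples=new_case, ref_samples=new_ref
            )
            up, down = call_degs(de, p_threshold)
            for degs in (up, down):
                mask = np.zeros(len(universe_list), dtype=bool)
                for g in degs:
                    if g in uidx:
                        mask[uidx[g]] = True
                p = _vectorized_enrichment(membership, mask)
                min_p[:, ci] = np.minimum(min_p[:, ci], p)
        null_counts[b] = (min_p < sig_threshold).sum(axis=1)

    return PermutationNull(
        counts=pd.DataFrame(null_counts, columns=module_names),
        sig_threshold=sig_threshold,
        min_conditions=min_conditions,
        seed=seed,
    )


def fisher_method_meta(pvalues) -> MetaResult:
    """Combine independent study P-values: chi^2 = -2 sum(ln p), df = 2k."""
    ps = tuple(float(p) for p in pvalues)
    if len(ps) == 0:
        raise ValueError("need at least one p-value")
    if any(p <= 0 or p > 1 for p in ps):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = -2.0 * sum(math.log(p) for p in ps)
    df = 2 * len(ps)
    return MetaResult(
        pvalues=ps, chi2=chi2, df=df, combined_p=float(stats.chi2.sf(chi2, df))
    )


def correlation_enrichment(
    abundance: pd.DataFrame,
    cag_lengths: np.ndarray,
    modules: dict[str, TFModule],
    p_threshold: float = 0.01,
):
    """Module enrichment for CAG-length-correlated proteins.

    Per protein: Pearson correlation of abundance against per-sample CAG
    length with a two-sided t-based P-value; proteins significant at
    ``p_threshold`` are split by correlation sign and each signed set is
    tested against every module over the measured universe.  Constant rows
    are excluded (count reported).

    Returns ``(protein_stats, enrichment_table, n_excluded)``.
    """
    cag = np.asarray(cag_lengths, dtype=float)
    n = len(cag)
    if n < 3:
        raise ValueError("need at least 3 samples for correlation")
    if abundance.shape[1] != n:
        raise ValueError("abundance columns must match CAG length vector")
    vals = abundance.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    constant = sd == 0
    n_excluded = int(constant.sum())
    vals = vals[~constant]
    index = abundance.index[~constant]
    az = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, keepdims=True)
    cz = (cag - cag.mean()) / cag.std()
    r = az @ cz / n
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    protein_stats = pd.DataFrame({"r": r, "pvalue": p}, index=index)
    universe = set(index)
    pos = set(index[(p < p_threshold) & (r > 0)])
    neg = set(index[(p < p_threshold) & (r < 0)])
    rows = []
    for direction, sig in (("positive", pos), ("negative", neg)):
        for tf, module in modules.items():
            targets = set(module.targets) & universe
            if not targets:
                continue
            res = fisher_enrichment(
                targets, sig, universe,
                module_id=tf, condition="CAG-correlated", direction=direction,
            )
            rows.append(res.__dict__)
    return protein_stats, pd.DataFrame(rows), n_excluded


def overlap_test(set_a: set, set_b: set, universe: set):
    """Shared count, odds ratio and one-sided Fisher P for two sets."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a_set = set(set_a) & universe
    b_set = set(set_b) & universe
    a = len(a_set & b_set)
    b = len(a_set) - a
    c = len(b_set) - a
    d = len(universe) - a - b - c
    raw, _ = _odds_ratios(a, b, c, d)
    return a, raw, _fisher_one_sided(a, b, c, d)


def geneset_enrichment(
    modules: dict[str, TFModule],
    gene_sets: dict[str, set[str]],
    universe: set[str],
    set_size_bounds: tuple[int, int] = (10, 500),
) -> pd.DataFrame:
    """Fisher enrichment of modules against generic gene sets (GO, cell types).

    Gene sets are intersected with the universe first, then size bounds are
    applied (inclusive).  P-values are BH-adjusted across sets within each
    module.  Returns an empty table (with a warning) when no set passes.
    """
    lo, hi = set_size_bounds
    universe = set(universe)
    usable = {
        name: genes & universe
        for name, genes in ((n, set(g)) for n, g in gene_sets.items())
        if lo <= len(genes & universe) <= hi
    }
    if not usable:
        warnings.warn("no gene sets within size bounds", stacklevel=2)
        return pd.DataFrame(
            columns=["module", "condition", "direction", "a", "b", "c", "d",
                     "odds_ratio", "odds_ratio_display", "p", "p_bh"]
        )
    frames = []
    for tf, module in modules.items():
        rows = []
        for name, genes in sorted(usable.items()):
            res = fisher_enrichment(
                module, genes, universe,
                module_id=tf, condition=name, direction="geneset",
            )
            rows.append(res.__dict__)
        df = pd.DataFrame(rows)
        df["p_bh"] = multipletests(df["p"], method="fdr_bh")[1]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def signed_logp_matrix(enrichment: pd.DataFrame, floor: float = 1e-300) -> pd.DataFrame:
    """Heatmap-ready module x condition matrix of signed -log10 P.

    Per (module, condition) the stronger direction wins; the sign is positive
    for up-regulation enrichment and negative for down.
    """
    def _cell(grp):
        i = grp["p"].idxmin()
        sign = 1.0 if grp.loc[i, "direction"] == "up" else -1.0
        return sign * -np.log10(max(grp.loc[i, "p"], floor))

    cells = enrichment.groupby(["module", "condition"]).apply(
        _cell, include_groups=False
    )
    return cells.unstack("condition")
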