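"""Leave-one-out imputation accuracy for array scaffolds.

The evaluator answers the design question "how much does custom content
improve imputation?" by masking each panel sample in turn, imputing its
untyped sites from the remaining haplotypes using only the scaffold
(on-array) sites as observations, and correlating imputed dosages with the
true genotypes — stratified by population and MAF bin, and differenced
between a scaffold with and without the custom content.

The imputation engine is a self-contained haploid Li–Stephens-style hidden
Markov model: the hidden state is a reference haplotype; between adjacent
scaffold sites the state switches to a uniformly drawn haplotype with
probability ``1 − exp(−ρ·d)`` (``d`` in bp); emissions match the observed
allele with probability ``1 − ε``.  Posterior state probabilities come from
a scaled forward–backward pass at scaffold sites and are interpolated
linearly in physical distance at each evaluation site; the haplotype dosage
is the posterior-weighted reference allele, and the sample dosage the sum
over its two haplotypes.  The engine sits behind a small interface so an
external imputation tool can be substituted.  The evaluator itself is fully
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .panel_io import DataError, HaplotypePanel

DEFAULT_BINS = (0.005, 0.01, 0.05)


@dataclass
class LSParams:
    """Hidden-markov-model parameters of the imputation engine.

    ``emission_error`` (ε) absorbs mutation and genotyping error;
    ``switch_rate`` (ρ, per bp) controls haplotype-copying switch intensity;
    ``ref_cap`` optionally bounds the number of reference haplotypes used
    per focal sample (an evenly spaced deterministic subset), trading
    accuracy for speed on large panels.
    """

    emission_error: float = 0.01
    switch_rate: float = 1e-6
    ref_cap: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.emission_error < 0.5):
            raise DataError("emission_error must lie in (0, 0.5)")
        if self.switch_rate < 0:
            raise DataError("switch_rate must be >= 0")
        if self.ref_cap is not None and self.ref_cap < 1:
            raise DataError("ref_cap must be >= 1")


@dataclass
class ScaffoldSpec:
    """A named set of typed (on-array) site ids."""

    name: str
    site_ids: set[str]


@dataclass
class ImputationReport:
    """Mean per-site accuracy (squared Pearson r × 100) per population × MAF bin."""

    accuracy: pd.DataFrame
    n_sites: pd.DataFrame
    n_excluded_low_maf: dict[str, int]
    n_excluded_zero_var: dict[str, int]
    observed_sites: set[str] = field(default_factory=set)


@dataclass
class ScaffoldComparison:
    with_report: ImputationReport
    without_report: ImputationReport
    delta: pd.DataFrame  # percentage points, with − without


# ----------------------------------------------------------------------
# HMM core
# ----------------------------------------------------------------------

def _forward_backward(
    ref_h: np.ndarray, obs: np.ndarray, p_switch: np.ndarray, eps: float
) -> np.ndarray:
    """Posterior over reference haplotypes at each scaffold site.

    ``ref_h``: (N, S) reference alleles; ``obs``: (S,) observed alleles;
    ``p_switch``: (S-1,) switch probabilities between adjacent sites.
    Returns (S, N) posteriors, each row summing to 1.
    """
    n, s = ref_h.shape
    em = np.where(ref_h == obs[None, :], 1.0 - eps, eps)  # (N, S)
    alpha = np.empty((s, n))
    beta = np.empty((s, n))
    scale = np.empty(s)

    a = em[:, 0] / n
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    for j in range(1, s):
        q = p_switch[j - 1]
        a = em[:, j] * ((1.0 - q) * alpha[j - 1] + q / n)
        scale[j] = a.sum()
        alpha[j] = a / scale[j]

    beta[s - 1] = 1.0
    for j in range(s - 2, -1, -1):
        q = p_switch[j]
        be = beta[j + 1] * em[:, j + 1]
        beta[j] = ((1.0 - q) * be + q * be.mean()) / scale[j + 1]

    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    return post


class _ChromPlan:
    """Per-chromosome column bookkeeping for one scaffold/eval layout."""

    def __init__(
        self,
        panel: HaplotypePanel,
        chrom: str,
        scaffold_cols: np.ndarray,
        eval_cols: np.ndarray,
        switch_rate: float,
    ):
        self.chrom = chrom
        self.scaffold_cols = scaffold_cols
        self.eval_cols = eval_cols
        pos = panel.positions
        spos = pos[scaffold_cols]
        epos = pos[eval_cols]
        if scaffold_cols.size == 0:
            raise DataError(
                f"no scaffold sites on chromosome {chrom} but evaluation sites present"
            )
        self.p_switch = 1.0 - np.exp(-switch_rate * np.diff(spos).astype(float))
        # linear-interpolation neighbors of each eval site among scaffold sites
        right = np.searchsorted(spos, epos)
        left = np.clip(right - 1, 0, len(spos) - 1)
        right = np.clip(right, 0, len(spos) - 1)
        gap = spos[right] - spos[left]
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(gap > 0, (epos - spos[left]) / gap, 0.0)
        self.left = left
        self.right = right
        self.weight = np.clip(w, 0.0, 1.0)


def _build_plans(
    panel: HaplotypePanel,
    scaffold_vids: Sequence[str],
    eval_vids: Sequence[str],
    switch_rate: float,
) -> list[_ChromPlan]:
    missing = [v for v in list(scaffold_vids) + list(eval_vids) if v not in panel.vid_index]
    if missing:
        raise DataError(f"sites absent from panel: {missing[:5]}")
    chroms = list(dict.fromkeys(panel.chroms))
    plans = []
    for chrom in chroms:
        scols = np.array(
            sorted(
                panel.vid_index[v]
                for v in scaffold_vids
                if panel.site(v).chrom == chrom
            ),
            dtype=np.intp,
        )
        ecols = np.array(
            sorted(
                panel.vid_index[v] for v in eval_vids if panel.site(v).chrom == chrom
            ),
            dtype=np.intp,
        )
        if ecols.size == 0:
            continue
        plans.append(_ChromPlan(panel, chrom, scols, ecols, switch_rate))
    return plans


def _ref_rows(n_samples: int, focal_sample: int, cap: Optional[int]) -> np.ndarray:
    rows = np.delete(
        np.arange(2 * n_samples), [2 * focal_sample, 2 * focal_sample + 1]
    )
    if cap is not None and rows.size > cap:
        pick = np.linspace(0, rows.size - 1, cap).round().astype(np.intp)
        rows = rows[np.unique(pick)]
    return rows


def impute_dosage(
    reference: HaplotypePanel,
    observed: np.ndarray,
    scaffold_vids: Sequence[str],
    eval_vids: Sequence[str],
    ls: LSParams,
) -> tuple[dict[str, float], set[str]]:
    """Impute alt-allele dosages for one sample's evaluation sites.

    ``reference`` must already exclude the focal sample; ``observed`` holds
    the focal sample's phased alleles at ``scaffold_vids`` with shape
    ``(2, len(scaffold_vids))``.  Evaluation sites that are themselves on
    the scaffold are returned at their observed dosage and reported in the
    second return value.
    """
    observed = np.asarray(observed)
    if observed.shape != (2, len(scaffold_vids)):
        raise DataError(
            f"observed shape {observed.shape} != (2, {len(scaffold_vids)})"
        )
    scaffold_set = set(scaffold_vids)
    plans = _build_plans(reference, scaffold_vids, eval_vids, ls.switch_rate)
    obs_col = {v: k for k, v in enumerate(scaffold_vids)}
    dosages: dict[str, float] = {}
    flagged: set[str] = set()
    for plan in plans:
        ref_s = reference.alleles[:, plan.scaffold_cols]
        ref_e = reference.alleles[:, plan.eval_cols].astype(float)
        svids = [reference.sites[j].vid for j in plan.scaffold_cols]
        obs_local = observed[:, [obs_col[v] for v in svids]]
        total = np.zeros(plan.eval_cols.size)
        for hap in range(2):
            post = _forward_backward(
                ref_s, obs_local[hap], plan.p_switch, ls.emission_error
            )
            pe = (
                post[plan.left] * (1.0 - plan.weight[:, None])
                + post[plan.right] * plan.weight[:, None]
            )
            total += (pe * ref_e.T).sum(axis=1)
        for k, j in enumerate(plan.eval_cols):
            vid = reference.sites[j].vid
            if vid in scaffold_set:
                flagged.add(vid)
                dosages[vid] = float(observed[:, obs_col[vid]].sum())
            else:
                dosages[vid] = float(np.clip(total[k], 0.0, 2.0))
    return dosages, flagged


# ----------------------------------------------------------------------
# Leave-one-out evaluation
# ----------------------------------------------------------------------

def _bin_label(edges: Sequence[float], i: int) -> str:
    pct = lambda x: f"{x * 100:g}%"
    if i < len(edges) - 1:
        return f"{pct(edges[i])}-{pct(edges[i + 1])}"
    return f">{pct(edges[-1])}"


def bin_labels(edges: Sequence[float] = DEFAULT_BINS) -> list[str]:
    return [_bin_label(edges, i) for i in range(len(edges))]


def _loo_dosages(
    panel: HaplotypePanel,
    scaffold_vids: list[str],
    eval_vids: list[str],
    ls: LSParams,
) -> tuple[np.ndarray, set[str]]:
    """Dosage matrix (n_samples × n_eval) from leave-one-out imputation."""
    plans = _build_plans(panel, scaffold_vids, eval_vids, ls.switch_rate)
    eval_order = [
        panel.sites[j].vid for plan in plans for j in plan.eval_cols
    ]
    col_of = {v: k for k, v in enumerate(eval_order)}
    scaffold_set = set(scaffold_vids)
    dmat = np.zeros((panel.n_samples, len(eval_vids)))
    out_col = np.array([col_of[v] for v in eval_vids], dtype=np.intp)
    flagged: set[str] = set()

    for plan in plans:
        ref_s_all = panel.alleles[:, plan.scaffold_cols]
        ref_e_all = panel.alleles[:, plan.eval_cols].astype(float)
        in_scaffold = np.array(
            [panel.sites[j].vid in scaffold_set for j in plan.eval_cols]
        )
        flagged |= {
            panel.sites[j].vid
            for j, m in zip(plan.eval_cols, in_scaffold)
            if m
        }
        local_out = np.array(
            [col_of[panel.sites[j].vid] for j in plan.eval_cols], dtype=np.intp
        )
        for i in range(panel.n_samples):
            rows = _ref_rows(panel.n_samples, i, ls.ref_cap)
            ref_s = ref_s_all[rows]
            ref_e = ref_e_all[rows]
            total = np.zeros(plan.eval_cols.size)
            for hap in (2 * i, 2 * i + 1):
                post = _forward_backward(
                    ref_s, ref_s_all[hap], plan.p_switch, ls.emission_error
                )
                pe = (
                    post[plan.left] * (1.0 - plan.weight[:, None])
                    + post[plan.right] * plan.weight[:, None]
                )
                total += (pe * ref_e.T).sum(axis=1)
            # observed (scaffold) eval sites come back at truth
            truth = ref_e_all[2 * i] + ref_e_all[2 * i + 1]
            total = np.where(in_scaffold, truth, np.clip(total, 0.0, 2.0))
            dmat[i, local_out] = total

    return dmat[:, out_col] if eval_order != eval_vids else dmat, flagged


def loo_accuracy(
    panel: HaplotypePanel,
    scaffold: ScaffoldSpec,
    eval_sites: Sequence[str],
    ls: Optional[LSParams] = None,
    bins: Sequence[float] = DEFAULT_BINS,
    statistic: str = "r2",
) -> ImputationReport:
    """Leave-one-out imputation accuracy stratified by population and MAF.

    For each sample in turn its haplotypes are dropped from the reference
    and its evaluation-site dosages imputed from scaffold observations.
    Per population and evaluation site, accuracy is the squared Pearson
    correlation (×100) between imputed dosages and true 0/1/2 genotypes
    across the population's samples (``statistic="r"`` reports plain r).
    Sites with population MAF below the lowest bin edge, or with zero
    dosage/genotype variance in a population, are excluded and counted.
    Populations with fewer than 3 samples report NA.
    """
    ls = ls or LSParams()
    eval_vids = list(eval_sites)
    scaffold_vids = sorted(
        scaffold.site_ids, key=lambda v: (panel.site(v).chrom, panel.site(v).pos)
    )
    missing = scaffold.site_ids - set(panel.vid_index)
    if missing:
        raise DataError(f"scaffold sites absent from panel: {sorted(missing)[:5]}")
    dmat, flagged = _loo_dosages(panel, scaffold_vids, eval_vids, ls)

    eval_cols = np.array([panel.vid_index[v] for v in eval_vids], dtype=np.intp)
    geno = (
        panel.alleles[0::2][:, eval_cols].astype(float)
        + panel.alleles[1::2][:, eval_cols]
    )
    pops = panel.populations()
    labels = bin_labels(bins)
    acc = pd.DataFrame(np.nan, index=pd.Index(pops, name="population"), columns=labels)
    nsites = pd.DataFrame(0, index=acc.index, columns=labels)
    n_low: dict[str, int] = {}
    n_zero: dict[str, int] = {}

    for pop in pops:
        sample_rows = np.array(
            [i for i, (_, p) in enumerate(panel.samples) if p == pop], dtype=np.intp
        )
        n_low[pop] = 0
        n_zero[pop] = 0
        if sample_rows.size < 3:
            continue
        g = geno[sample_rows]
        d = dmat[sample_rows]
        f = g.mean(axis=0) / 2.0
        mafs = np.minimum(f, 1.0 - f)
        per_bin: dict[str, list[float]] = {lb: [] for lb in labels}
        for e in range(len(eval_vids)):
            m = mafs[e]
            if m < bins[0]:
                n_low[pop] += 1
                continue
            gv, dv = g[:, e], d[:, e]
            if gv.std() == 0 or dv.std() == 0:
                n_zero[pop] += 1
                continue
            r = float(np.corrcoef(dv, gv)[0, 1])
            val = r * 100.0 if statistic == "r" else r * r * 100.0
            # right-closed bins: [e0, e1], (e1, e2], ..., (e_last, 0.5]
            k = int(np.searchsorted(bins[1:], m, side="left"))
            per_bin[labels[k]].append(val)
        for lb in labels:
            if per_bin[lb]:
                acc.loc[pop, lb] = float(np.mean(per_bin[lb]))
                nsites.loc[pop, lb] = len(per_bin[lb])

    return ImputationReport(acc, nsites, n_low, n_zero, flagged)


def compare_scaffolds(
    panel: HaplotypePanel,
    with_custom: ScaffoldSpec,
    without_custom: ScaffoldSpec,
    eval_sites: Sequence[str],
    ls: Optional[LSParams] = None,
    bins: Sequence[float] = DEFAULT_BINS,
) -> ScaffoldComparison:
    """Accuracy difference (percentage points) between two nested scaffolds.

    ``without_custom`` must be a subset of ``with_custom`` and the
    evaluation sites disjoint from ``with_custom``; both runs use identical
    evaluation sites and samples.
    """
    if not without_custom.site_ids <= with_custom.site_ids:
        raise DataError("without_custom scaffold must be a subset of with_custom")
    overlap = set(eval_sites) & with_custom.site_ids
    if overlap:
        raise DataError(
            f"evaluation sites overlap the with_custom scaffold: {sorted(overlap)[:5]}"
        )
    rep_with = loo_accuracy(panel, with_custom, eval_sites, ls, bins)
    rep_without = loo_accuracy(panel, without_custom, eval_sites, ls, bins)
    delta = rep_with.accuracy - rep_without.accuracy
    return ScaffoldComparison(rep_with, rep_without, delta)
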