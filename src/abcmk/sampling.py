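"""Poisson sampling of divergence and polymorphism, and the synthetic
dataset generator.

Counts of fixed differences and of polymorphic sites per frequency bin are
treated as independent Poisson variables whose means come from the analytic
expectations (a Poisson random field).  Two uses:

* conditioning on an *observed* dataset's totals to simulate summary
  statistics for ABC (process variance via Poisson, sampling variance via the
  binomial projection already folded into the expected spectra), and
* generating complete synthetic datasets from scratch under a solved
  scenario, standing in for forward simulations.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ExpectedRates, ExpectedSpectra, downsample_binomial, expected_sfs_point
from .solver import SolvedScenario

__all__ = [
    "ObservedCounts",
    "sample_fixations",
    "sample_polymorphism",
    "split_observed_sfs",
    "split_observed_divergence",
    "generate_dataset",
    "SyntheticDataset",
]

_FIX_CLASSES = ("neutral", "deleterious", "weak", "strong")


@dataclass
class ObservedCounts:
    """Unfolded SFS and divergence counts for one gene or a pooled set."""

    sfs_nonsyn: np.ndarray
    sfs_syn: np.ndarray
    DN: int
    DS: int
    n: int

    def __post_init__(self):
        self.sfs_nonsyn = np.asarray(self.sfs_nonsyn)
        self.sfs_syn = np.asarray(self.sfs_syn)
        expected = 2 * self.n - 1
        if self.sfs_nonsyn.shape != (expected,) or self.sfs_syn.shape != (expected,):
            raise ValueError(
                f"SFS vectors must have length 2n-1={expected}, got "
                f"{self.sfs_nonsyn.shape} and {self.sfs_syn.shape}"
            )
        if self.DN < 0 or self.DS < 0:
            raise ValueError("divergence counts must be non-negative")
        if np.any(self.sfs_nonsyn < 0) or np.any(self.sfs_syn < 0):
            raise ValueError("SFS counts must be non-negative")

    @property
    def PN(self) -> int:
        return int(self.sfs_nonsyn.sum())

    @property
    def PS(self) -> int:
        return int(self.sfs_syn.sum())

    @staticmethod
    def pooled(genes: "list[ObservedCounts]") -> "ObservedCounts":
        if not genes:
            raise ValueError("cannot pool an empty gene list")
        n = genes[0].n
        if any(g.n != n for g in genes):
            raise ValueError("all genes must share the same sample size")
        return ObservedCounts(
            sfs_nonsyn=np.sum([g.sfs_nonsyn for g in genes], axis=0),
            sfs_syn=np.sum([g.sfs_syn for g in genes], axis=0),
            DN=sum(g.DN for g in genes),
            DS=sum(g.DS for g in genes),
            n=n,
        )


def sample_fixations(
    D_total: int, rates: ExpectedRates, rng: np.random.Generator
) -> dict[str, int]:
    """Poisson-sample nonsynonymous fixation counts by fitness class.

    Each class mean is ``D_total`` times its share of the total expected
    nonsynonymous fixation rate, so class means sum to ``D_total``.
    """
    if D_total < 0:
        raise ValueError("D_total must be non-negative")
    comps = np.array([rates.d0, rates.d_neg, rates.d_weak, rates.d_strong])
    if D_total == 0:
        return dict.fromkeys(_FIX_CLASSES, 0)
    lam = D_total * comps / comps.sum()
    draws = rng.poisson(lam)
    return dict(zip(_FIX_CLASSES, (int(v) for v in draws)))


def sample_polymorphism(
    P_totals: tuple[float, float],
    spectra: ExpectedSpectra,
    rng: np.random.Generator,
    syn_spectrum: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Poisson-sample SFS vectors per class, conditioned on class totals.

    ``P_totals = (PN, PS)``; the nonsynonymous total is distributed across
    classes and frequency bins proportionally to the expected class spectra
    (already on the sample grid), the synonymous total across bins of the
    neutral spectrum.  Expected sampled totals equal the inputs.
    """
    PN, PS = P_totals
    if PN < 0 or PS < 0:
        raise ValueError("polymorphism totals must be non-negative")
    psi = {"neutral": spectra.psi0, "deleterious": spectra.psi_neg, "pos": spectra.psi_pos}
    nonsyn_mass = sum(v.sum() for v in psi.values())
    if PN > 0 and nonsyn_mass <= 0:
        raise ValueError("zero expected nonsynonymous spectrum with PN > 0")
    out = {}
    for name, vec in psi.items():
        lam = PN * vec / nonsyn_mass if PN > 0 else np.zeros_like(vec)
        out[name] = rng.poisson(lam)
    if syn_spectrum is None:
        n = (spectra.psi0.size + 1) // 2
        syn_spectrum = 1.0 / np.arange(1, 2 * n)  # neutral 1/i shape
    if PS > 0 and syn_spectrum.sum() <= 0:
        raise ValueError("zero expected synonymous spectrum with PS > 0")
    lam_s = PS * syn_spectrum / syn_spectrum.sum() if PS > 0 else np.zeros_like(syn_spectrum)
    out["syn"] = rng.poisson(lam_s)
    return out


def split_observed_sfs(
    total_sfs: np.ndarray,
    psi_nonsyn: np.ndarray,
    psi_syn: np.ndarray,
    nonsyn_fraction: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin split of the observed total SFS into N and S classes.

    The observed number of polymorphic sites at each frequency is kept (it
    carries the demography the analytic model does not describe); the model
    decides, bin by bin, the expected nonsynonymous share, and Poisson noise
    supplies the process variance.
    """
    wN = nonsyn_fraction * psi_nonsyn
    wS = (1.0 - nonsyn_fraction) * psi_syn
    share = np.divide(wN, wN + wS, out=np.zeros_like(wN), where=(wN + wS) > 0)
    pn = rng.poisson(total_sfs * share)
    ps = rng.poisson(total_sfs * (1.0 - share))
    return pn, ps


def split_observed_divergence(
    D_total: int,
    rate_nonsyn: float,
    rate_syn: float,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Split the observed total fixation count into DN and DS by the
    model's relative per-site substitution rates."""
    tot = rate_nonsyn + rate_syn
    dn = int(rng.poisson(D_total * rate_nonsyn / tot))
    ds = int(rng.poisson(D_total * rate_syn / tot))
    return dn, ds


@dataclass
class SyntheticDataset:
    """Synthetic pooled dataset with its class-labelled truth."""

    pooled: ObservedCounts
    class_sfs: dict[str, np.ndarray]        # nonsynonymous sample SFS by class
    class_divergence: dict[str, int]        # nonsynonymous fixations by class
    alpha_true: float
    alpha_weak_true: float
    genes: pd.DataFrame | None = None       # per-gene DN/DS/PN/PS totals
    gene_counts: list[ObservedCounts] | None = None

    @property
    def nonsyn_minus(self) -> ObservedCounts:
        """The dataset with beneficial polymorphism removed (knowable only
        for synthetic data; used to quantify weak-selection bias)."""
        return ObservedCounts(
            sfs_nonsyn=self.class_sfs["deleterious"] + self.class_sfs["neutral"],
            sfs_syn=self.pooled.sfs_syn,
            DN=self.pooled.DN,
            DS=self.pooled.DS,
            n=self.pooled.n,
        )


def generate_dataset(
    scenario: SolvedScenario,
    n_genes: int,
    seed: int,
    L_coding: int = 2000,
    divergence_scale: float = 0.01,
    per_gene: bool = False,
    full_gene_counts: bool = False,
) -> SyntheticDataset:
    """Generate a pooled synthetic dataset under a solved scenario.

    Each of ``n_genes`` coding loci of ``L_coding`` bp contributes Poisson
    fixation counts (mean ``divergence_scale`` substitutions per neutral site
    along the branch) and Poisson polymorphism per frequency bin from the
    scenario's expected sample spectra.  Because sums of independent Poisson
    draws are Poisson, the pooled dataset is drawn directly at pooled means;
    ``per_gene`` adds per-gene divergence/polymorphism totals and
    ``full_gene_counts`` materialises per-gene SFS vectors (memory-heavy,
    intended for modest ``n_genes``).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    model = scenario.model
    rates = scenario.rates()  # at the scenario's B
    fr_n = model.nonsyn_fraction
    Ln = fr_n * L_coding * n_genes
    Ls = (1.0 - fr_n) * L_coding * n_genes

    # expected fixations per site: divergence_scale * 2N * d_class
    fix_factor = divergence_scale * 2.0 * model.N
    lam_div = {
        "neutral": Ln * fix_factor * rates.d0,
        "deleterious": Ln * fix_factor * rates.d_neg,
        "weak": Ln * fix_factor * rates.d_weak,
        "strong": Ln * fix_factor * rates.d_strong,
    }
    lam_ds = Ls * fix_factor / (2.0 * model.N * model.B)

    # the population spectrum is a density in x; expected counts per
    # population-frequency bin carry the grid spacing 1/(2N)
    dx = 1.0 / (2.0 * model.N)
    sp = scenario.spectra(downsample=True)
    psi_syn = downsample_binomial(
        expected_sfs_point(0.0, model.theta_coding * model.B, model.N), model.n
    )
    lam_sfs = {
        "neutral": Ln * dx * sp.psi0,
        "deleterious": Ln * dx * sp.psi_neg,
        "weak": Ln * dx * downsample_binomial(
            model.frac_weak
            * expected_sfs_point(model.B * model.s_weak, model.theta_coding * model.B, model.N),
            model.n,
        ),
        "strong": Ln * dx * downsample_binomial(
            model.frac_strong
            * expected_sfs_point(model.B * model.s_strong, model.theta_coding * model.B, model.N),
            model.n,
        ),
    }
    lam_ps = Ls * dx * psi_syn

    class_div = {k: int(rng.poisson(v)) for k, v in lam_div.items()}
    DS = int(rng.poisson(lam_ds))
    class_sfs = {k: rng.poisson(v) for k, v in lam_sfs.items()}
    pooled = ObservedCounts(
        sfs_nonsyn=sum(class_sfs.values()),
        sfs_syn=rng.poisson(lam_ps),
        DN=sum(class_div.values()),
        DS=DS,
        n=model.n,
    )
    alpha, alpha_weak, _ = rates.alpha, rates.alpha_weak, rates.alpha_strong
    ds = SyntheticDataset(
        pooled=pooled,
        class_sfs=class_sfs,
        class_divergence=class_div,
        alpha_true=alpha,
        alpha_weak_true=alpha_weak,
    )
    if per_gene or full_gene_counts:
        lam_dn_gene = sum(lam_div.values()) / n_genes
        lam_ds_gene = lam_ds / n_genes
        lam_pn_gene = sum(v.sum() for v in lam_sfs.values()) / n_genes
        lam_ps_gene = lam_ps.sum() / n_genes
        ds.genes = pd.DataFrame(
            {
                "gene_id": [f"g{i:06d}" for i in range(n_genes)],
                "DN": rng.poisson(lam_dn_gene, n_genes),
                "DS": rng.poisson(lam_ds_gene, n_genes),
                "PN": rng.poisson(lam_pn_gene, n_genes),
                "PS": rng.poisson(lam_ps_gene, n_genes),
            }
        )
    if full_gene_counts:
        lam_n_gene = sum(lam_sfs.values()) / n_genes
        lam_s_gene = lam_ps / n_genes
        ds.gene_counts = [
            ObservedCounts(
                sfs_nonsyn=rng.poisson(lam_n_gene),
                sfs_syn=rng.poisson(lam_s_gene),
                DN=int(rng.poisson(lam_dn_gene)),
                DS=int(rng.poisson(lam_ds_gene)),
                n=model.n,
            )
            for _ in range(n_genes)
        ]
    return ds
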