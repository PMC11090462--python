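"""Readers, writers and configuration.

The native polymorphism format is TSV of pre-aggregated unfolded SFS counts
(the method consumes counts by derived allele class, not genotypes).  Two
encodings are accepted:

* wide — one row per gene: ``gene_id  DN  DS  nonsyn_1 .. nonsyn_{2n-1}
  syn_1 .. syn_{2n-1}`` (derived-allele-count indexing is 1-based), and
* long — one row per gene and derived allele count: ``gene_id  DN  DS
  daf_count  nonsyn  syn`` (divergence repeated on each row).

Output files embed the package version, seed and settings as ``#`` header
comments so every result is reproducible from its own header.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .sampling import ObservedCounts
from .solver import PriorSpec

__all__ = [
    "AnalysisConfig",
    "load_config",
    "read_sfs_divergence",
    "write_sfs_divergence",
    "write_grid",
    "read_grid",
]

_WIDE_HEAD = ["gene_id", "DN", "DS"]
_LONG_COLS = ["gene_id", "DN", "DS", "daf_count", "nonsyn", "syn"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Declarative analysis settings; CLI flags override these."""

    N: int = 500
    n: int = 500
    n_draws: int = 100_000
    seed: int = 1
    tolerance: float = 0.025
    max_daf: float = 0.7
    b_bin_width: float = 0.025
    x_grid: tuple[int, ...] | None = None
    alpha_prior: tuple[float, float] = (0.0, 0.9)
    s_weak_prior: tuple[float, float] = (1.0, 10.0)
    s_strong_prior: tuple[float, float] = (200.0, 2000.0)
    gam_mean_prior: tuple[float, float] = (200.0, 1000.0)
    shape_log2_prior: tuple[float, float] = (-2.0, 2.0)
    t_mag_prior: tuple[float, float] = (500.0, 1000.0)
    B_prior: tuple[float, float] = (0.1, 0.999)

    def priors(self) -> PriorSpec:
        return PriorSpec(
            alpha=self.alpha_prior,
            s_weak=self.s_weak_prior,
            s_strong=self.s_strong_prior,
            gam_mean=self.gam_mean_prior,
            shape_log2=self.shape_log2_prior,
            t_mag=self.t_mag_prior,
            B=self.B_prior,
            N=self.N,
            n=self.n,
        )


def load_config(path) -> AnalysisConfig:
    """Load a YAML config, rejecting unknown keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for f in dataclasses.fields(AnalysisConfig):
        if f.name in raw and isinstance(raw[f.name], list):
            raw[f.name] = tuple(raw[f.name])
    return AnalysisConfig(**raw)


def _header(seed=None, **settings) -> str:
    from . import __version__

    parts = [f"# abcmk v{__version__}"]
    if seed is not None:
        parts.append(f"# seed={seed}")
    for k, v in settings.items():
        parts.append(f"# {k}={v}")
    return "\n".join(parts) + "\n"


def write_sfs_divergence(path, genes: list[ObservedCounts], gene_ids=None, seed=None):
    """Write per-gene counts in the wide TSV encoding."""
    if not genes:
        raise ValueError("nothing to write")
    n = genes[0].n
    if gene_ids is None:
        gene_ids = [f"g{i:06d}" for i in range(len(genes))]
    k = 2 * n - 1
    cols = _WIDE_HEAD + [f"nonsyn_{i}" for i in range(1, k + 1)] + [
        f"syn_{i}" for i in range(1, k + 1)
    ]
    rows = [
        [gid, g.DN, g.DS, *g.sfs_nonsyn.tolist(), *g.sfs_syn.tolist()]
        for gid, g in zip(gene_ids, genes)
    ]
    df = pd.DataFrame(rows, columns=cols)
    with open(path, "w") as fh:
        fh.write(_header(seed=seed, n=n, format="wide", daf_indexing="1-based"))
        df.to_csv(fh, sep="\t", index=False)


def _fail(path, line, msg):
    raise ValueError(f"{path}: line {line}: {msg}")


def read_sfs_divergence(path) -> tuple[ObservedCounts, list[ObservedCounts]]:
    """Read a wide- or long-format counts TSV.

    Returns the pooled counts and the per-gene records.  Raises descriptive
    errors (with line numbers) for missing headers, ragged rows, negative
    counts or an SFS whose length disagrees with the inferred sample size.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    if list(df.columns[:3]) != _WIDE_HEAD:
        raise ValueError(
            f"{path}: header must start with {_WIDE_HEAD}, got {list(df.columns[:3])}"
        )
    long_format = list(df.columns) == _LONG_COLS
    genes: list[ObservedCounts] = []
    if long_format:
        for gid, sub in df.groupby("gene_id", sort=False):
            line = int(sub.index[0]) + 2
            counts = sub[["daf_count", "nonsyn", "syn"]].to_numpy()
            k = int(counts[:, 0].max())
            if k % 2 == 0:
                _fail(path, line, f"max daf_count {k} is even; expected 2n-1 classes")
            n = (k + 1) // 2
            sfs_n = np.zeros(k, dtype=int)
            sfs_s = np.zeros(k, dtype=int)
            if np.any(counts < 0):
                _fail(path, line, "negative count")
            sfs_n[counts[:, 0].astype(int) - 1] = counts[:, 1]
            sfs_s[counts[:, 0].astype(int) - 1] = counts[:, 2]
            genes.append(
                ObservedCounts(sfs_n, sfs_s, int(sub["DN"].iloc[0]), int(sub["DS"].iloc[0]), n)
            )
        if len({g.n for g in genes}) > 1:
            raise ValueError(f"{path}: genes disagree on sample size 2n")
    else:
        ncols = df.shape[1] - 3
        if ncols < 2 or ncols % 2 != 0:
            raise ValueError(
                f"{path}: expected paired nonsyn_*/syn_* columns, found {ncols}"
            )
        k = ncols // 2
        if k % 2 == 0:
            raise ValueError(f"{path}: {k} SFS classes is even; expected 2n-1")
        n = (k + 1) // 2
        expect = _WIDE_HEAD + [f"nonsyn_{i}" for i in range(1, k + 1)] + [
            f"syn_{i}" for i in range(1, k + 1)
        ]
        if list(df.columns) != expect:
            raise ValueError(f"{path}: malformed wide header (expected {expect[:5]}...)")
        for row_i, row in enumerate(df.itertuples(index=False), start=2):
            vals = np.asarray(row[1:], dtype=float)
            if np.any(vals < 0):
                _fail(path, row_i, "negative count")
            if np.any(vals != np.floor(vals)):
                _fail(path, row_i, "non-integer count")
            genes.append(
                ObservedCounts(
                    np.asarray(row[3 : 3 + k], dtype=int),
                    np.asarray(row[3 + k :], dtype=int),
                    int(row[1]),
                    int(row[2]),
                    n,
                )
            )
    return ObservedCounts.pooled(genes), genes


def write_grid(path, grid: pd.DataFrame):
    """Write the solved parameter grid with its provenance header."""
    with open(path, "w") as fh:
        fh.write(_header(seed=grid.attrs.get("seed"), priors=grid.attrs.get("priors")))
        grid.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_grid(path, priors: PriorSpec | None = None) -> pd.DataFrame:
    grid = pd.read_csv(path, sep="\t", comment="#")
    grid.attrs["priors"] = priors or PriorSpec()
    return grid
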