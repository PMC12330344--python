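"""End-to-end screening: I/O, gene filters, pair enumeration, fitting loop.

Counts are genes x cells, either a 10x-style MTX triplet (matrix.mtx,
features.tsv, barcodes.tsv) or a dense TSV/CSV with gene names in the
first column and barcodes in the header.  Cell metadata is a TSV with
columns cell_id, patient, group and optionally depth; when depth is absent
it is taken as the per-cell total over all genes of the supplied matrix,
so filters should be applied after depth computation (`screen` handles
this).
"""

from __future__ import annotations

import itertools
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import GenePairData
from .design import ModelSpec
from .fitting import FitControl, fit
from .inference import bh_adjust, natural_scale_rho, wald

__all__ = [
    "enumerate_pairs", "filter_genes", "make_pair_data", "read_counts",
    "read_metadata", "screen", "top_table",
]

SCREEN_COLUMNS = ["gene1", "gene2", "rho_g0", "rho_g1", "abs_delta_rho",
                  "tau1", "se", "p", "p_bh", "converged"]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_counts(path, fmt: str | None = None) -> pd.DataFrame:
    """Read a genes x cells integer count matrix.

    ``fmt`` is 'mtx' (triplet directory or matrix.mtx path) or 'dense'
    (TSV/CSV); when None it is inferred from the path.
    """
    path = Path(path)
    if fmt is None:
        if path.is_dir() or path.suffix == ".mtx":
            fmt = "mtx"
        else:
            fmt = "dense"
    if fmt == "mtx":
        from scipy import io as spio
        d = path if path.is_dir() else path.parent
        mat = spio.mmread(str(d / "matrix.mtx"))
        genes = pd.read_csv(d / "features.tsv", sep="\t", header=None
                            ).iloc[:, 0].astype(str).tolist()
        cells = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None
                            ).iloc[:, 0].astype(str).tolist()
        df = pd.DataFrame(np.asarray(mat.todense()), index=genes,
                          columns=cells)
    elif fmt == "dense":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        df.index = df.index.astype(str)
    else:
        raise ValueError(f"unknown counts format {fmt!r}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError("count matrix contains non-numeric entries")
    if np.any(arr != np.floor(arr)) or np.any(arr < 0):
        raise ValueError("count matrix must contain non-negative integers")
    return df.astype(np.int64)


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    required = {"cell_id", "patient", "group"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    meta["cell_id"] = meta["cell_id"].astype(str)
    return meta


def _align(counts: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in counts.columns if c not in set(metadata["cell_id"])]
    if missing:
        raise ValueError(f"metadata missing barcode {missing[0]!r} "
                         f"({len(missing)} barcodes unmatched)")
    aligned = metadata.set_index("cell_id").loc[counts.columns]
    aligned.index.name = "cell_id"
    return aligned.reset_index()


# ---------------------------------------------------------------------------
# gene filtering
# ---------------------------------------------------------------------------

def _upper_quantile(values: np.ndarray, q: float = 0.975) -> float:
    """Nearest-rank (type-1) empirical quantile; reproducible on integers."""
    v = np.sort(np.asarray(values))
    k = int(np.ceil(q * len(v))) - 1
    return float(v[max(k, 0)])


def default_normalization(counts: pd.DataFrame) -> pd.DataFrame:
    """Fallback normalization: log1p of depth-scaled counts.

    Each cell is scaled by median(depth)/depth before log1p, so the
    variance filters are not driven by sequencing-depth differences.  An
    externally normalized matrix can be supplied instead.
    """
    depth = counts.sum(axis=0).to_numpy().astype(float)
    scale = np.median(depth) / np.maximum(depth, 1.0)
    return np.log1p(counts * scale)


def filter_genes(counts: pd.DataFrame, exclude=(), mode: str = "droplet",
                 group=None, normalized: pd.DataFrame | None = None,
                 zero_fraction_max: float = 0.70, quantile_min: float = 4.0,
                 sd_min: float = 0.4, sd_diff_min: float = 0.1) -> list:
    """Apply the screening gene filters; returns retained genes in order.

    Both modes drop excluded-list genes, genes with more than 70% zero
    counts, and genes whose 97.5% upper quantile is below 4.  Plate mode
    additionally drops genes whose normalized expression has standard
    deviation below 0.4 in either group, or whose between-group absolute
    SD difference is below 0.1 (requires group labels; uses
    `default_normalization` when no normalized matrix is given).
    """
    if mode not in ("droplet", "plate"):
        raise ValueError(f"unknown mode {mode!r}")
    excluded = set()
    for lst in exclude:
        if isinstance(lst, (str, Path)):
            lst = [ln.strip() for ln in Path(lst).read_text().splitlines()
                   if ln.strip()]
        excluded |= set(lst)
    arr = counts.to_numpy()
    keep = []
    zero_frac = (arr == 0).mean(axis=1)
    if mode == "plate":
        if group is None:
            raise ValueError("plate mode requires group labels")
        group = np.asarray(group)
        norm = normalized if normalized is not None \
            else default_normalization(counts)
        norm = norm.loc[counts.index]
        levels = sorted(pd.unique(group).tolist(), key=str)
        if len(levels) != 2:
            raise ValueError("plate-mode SD filter expects two groups")
        g0 = norm.loc[:, group == levels[0]].std(axis=1, ddof=1)
        g1 = norm.loc[:, group == levels[1]].std(axis=1, ddof=1)
    for i, gene in enumerate(counts.index):
        if gene in excluded:
            continue
        if zero_frac[i] > zero_fraction_max:
            continue
        if _upper_quantile(arr[i]) < quantile_min:
            continue
        if mode == "plate":
            s0, s1 = float(g0.iloc[i]), float(g1.iloc[i])
            if s0 < sd_min or s1 < sd_min or abs(s0 - s1) < sd_diff_min:
                continue
        keep.append(gene)
    return keep


def enumerate_pairs(genes) -> list:
    """All n(n-1)/2 unordered gene pairs in lexicographic order."""
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("need at least two genes to form pairs")
    return list(itertools.combinations(sorted(genes), 2))


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

def make_pair_data(counts: pd.DataFrame, metadata: pd.DataFrame,
                   gene1: str, gene2: str,
                   depth: np.ndarray | None = None) -> GenePairData:
    meta = _align(counts, metadata)
    if depth is None:
        if "depth" in meta.columns:
            depth = meta["depth"].to_numpy().astype(float)
        else:
            depth = counts.sum(axis=0).to_numpy().astype(float)
    cov_cols = [c for c in meta.columns
                if c not in ("cell_id", "patient", "depth")]
    return GenePairData(
        y1=counts.loc[gene1].to_numpy(), y2=counts.loc[gene2].to_numpy(),
        patient=meta["patient"].to_numpy(), covariates=meta[cov_cols],
        depth=depth, cell_ids=meta["cell_id"].to_numpy(),
        gene_names=(gene1, gene2))


def _fit_one(counts, metadata, g1, g2, spec, control, condition):
    data = make_pair_data(counts, metadata, g1, g2)
    row = dict(gene1=g1, gene2=g2, rho_g0=np.nan, rho_g1=np.nan,
               abs_delta_rho=np.nan, tau1=np.nan, se=np.nan, p=np.nan,
               converged=False)
    try:
        res = fit(data, spec, control)
        test = wald(res, f"rho.{condition}")
        r0, r1, dr = natural_scale_rho(res)
        row.update(rho_g0=r0, rho_g1=r1, abs_delta_rho=dr,
                   tau1=test.estimate, se=test.se, p=test.p,
                   converged=bool(res.converged))
    except Exception as exc:        # per-pair failures never abort the screen
        row["error"] = str(exc)
    return row


def screen(counts: pd.DataFrame, metadata: pd.DataFrame,
           spec: ModelSpec | None = None, control: FitControl | None = None,
           pairs=None, condition: str = "group",
           cache_dir=None, progress: bool = False) -> pd.DataFrame:
    """Fit every gene pair and assemble the BH-corrected screen table.

    Results are independent of pair processing order; with ``cache_dir``
    each pair's result is stored as JSON so an interrupted screen resumes
    where it stopped and a rerun reproduces the table bit-identically.
    """
    spec = spec or ModelSpec.two_group(condition=condition)
    pairs = pairs if pairs is not None else enumerate_pairs(counts.index)
    cache = Path(cache_dir) if cache_dir else None
    if cache:
        cache.mkdir(parents=True, exist_ok=True)
    rows = []
    iterator = pairs
    if progress:
        iterator = _progress(pairs)
    for g1, g2 in iterator:
        key = None
        if cache:
            key = cache / f"{g1}__{g2}.json"
            if key.exists():
                rows.append(json.loads(key.read_text()))
                continue
        row = _fit_one(counts, metadata, g1, g2, spec, control, condition)
        if key:
            key.write_text(json.dumps(row))
        rows.append(row)
    table = pd.DataFrame(rows)
    pvals = table["p"].where(table["converged"], np.nan)
    table["p_bh"] = bh_adjust(pvals.to_numpy())
    cols = SCREEN_COLUMNS + [c for c in table.columns
                             if c not in SCREEN_COLUMNS]
    return table[cols]


def _progress(seq):
    try:
        from tqdm import tqdm
        return tqdm(seq)
    except ImportError:             # pragma: no cover
        return seq


def top_table(table: pd.DataFrame, k: int = 25) -> pd.DataFrame:
    """Top-k converged pairs ranked by absolute co-expression change."""
    t = table[table["converged"]].sort_values(
        "abs_delta_rho", ascending=False, kind="mergesort")
    return t.head(k).reset_index(drop=True)
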