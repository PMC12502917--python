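"""Reading, preprocessing and assembling spatial transcriptomics studies.

A study is a collection of tissue slices, each carrying a spots x genes
expression matrix, 2-D spot coordinates, a binary per-spot disease label and
an observation indicator ``r``.  A spot with ``r = 0`` is *missing*: neither
its expression nor its label was captured (e.g. a region lost during tissue
slicing), and it enters the model only through label imputation.

Preprocessing follows the standard pipeline for this model family: genes
whose total count falls below a threshold are dropped, the surviving gene
sets are intersected so every slice carries the same genes, and counts are
mapped through ``log(x + 1)`` (natural log).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "SpatialSlice",
    "StudyDataset",
    "read_slice",
    "write_slice",
    "read_study",
    "write_study",
    "filter_genes",
    "log_transform",
]


@dataclass
class SpatialSlice:
    """One tissue slice.

    ``y`` is a float array with entries in {0, 1} at observed spots and NaN
    at missing spots; ``r`` is the 0/1 observation indicator, and
    ``r[i] == 0`` iff ``y[i]`` is NaN.  Rows of ``X`` at missing spots are
    zero placeholders and are never used by the likelihood.
    """

    donor_id: str
    slice_id: str
    coords: np.ndarray
    X: np.ndarray
    gene_names: list
    y: np.ndarray
    r: np.ndarray
    spot_ids: list = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.r = np.asarray(self.r, dtype=int)
        n = self.coords.shape[0]
        if self.spot_ids is None:
            self.spot_ids = [f"spot{i}" for i in range(n)]
        if not (self.X.shape[0] == self.y.shape[0] == self.r.shape[0] == n):
            raise ValueError("coords, X, y and r must agree on the number of spots")
        if self.X.shape[1] != len(self.gene_names):
            raise ValueError("X column count must match gene_names")
        miss = np.isnan(self.y)
        if not np.array_equal(miss, self.r == 0):
            raise ValueError("r[i] == 0 must hold exactly where y[i] is missing")
        obs_y = self.y[~miss]
        if obs_y.size and not np.isin(obs_y, (0.0, 1.0)).all():
            raise ValueError("observed labels must be binary 0/1")
        if not np.all(np.isfinite(self.X[self.r == 1])):
            raise ValueError("expression must be finite at observed spots")

    @property
    def n_spots(self) -> int:
        return self.coords.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    @property
    def observed(self) -> np.ndarray:
        return self.r == 1


@dataclass
class StudyDataset:
    """A multi-slice study; all slices share one gene list in one order."""

    slices: list
    truth: object = field(default=None, repr=False)

    def __post_init__(self):
        if not self.slices:
            raise ValueError("a study needs at least one slice")
        ref = self.slices[0].gene_names
        for s in self.slices[1:]:
            if s.gene_names != ref:
                raise ValueError(
                    "all slices must share an identical gene list in identical "
                    "order; run filter_genes to intersect them"
                )

    @property
    def gene_names(self) -> list:
        return self.slices[0].gene_names

    @property
    def donors(self) -> list:
        seen = {}
        for s in self.slices:
            seen.setdefault(s.donor_id, None)
        return list(seen)

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    def donor_slice_index(self):
        """(donor position, within-donor slice position) for every slice."""
        donors = self.donors
        pos = {d: 0 for d in donors}
        out = []
        for s in self.slices:
            c = donors.index(s.donor_id)
            out.append((c, pos[s.donor_id]))
            pos[s.donor_id] += 1
        return out


def _read_table(path):
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def _read_counts(counts_path):
    """Return (spot_ids, gene_names, dense counts spots x genes)."""
    counts_path = Path(counts_path)
    if counts_path.suffix == ".mtx":
        mat = scipy.io.mmread(counts_path)
        mat = scipy.sparse.csr_matrix(mat)
        base = counts_path.parent
        genes_file = next(
            (base / n for n in ("features.tsv", "genes.tsv", "features.txt", "genes.txt") if (base / n).exists()),
            None,
        )
        barcodes_file = next(
            (base / n for n in ("barcodes.tsv", "barcodes.txt") if (base / n).exists()),
            None,
        )
        if genes_file is None or barcodes_file is None:
            raise FileNotFoundError(
                "MTX counts need companion features/genes and barcodes files next to the .mtx"
            )
        genes = pd.read_csv(genes_file, sep="\t", header=None)[0].astype(str).tolist()
        barcodes = pd.read_csv(barcodes_file, sep="\t", header=None)[0].astype(str).tolist()
        # 10X convention stores features on rows; transpose to spots x genes
        if mat.shape == (len(genes), len(barcodes)):
            mat = mat.T
        elif mat.shape != (len(barcodes), len(genes)):
            raise ValueError("MTX shape matches neither genes x barcodes nor barcodes x genes")
        return barcodes, genes, np.asarray(mat.todense(), dtype=float)
    df = _read_table(counts_path)
    spot_col = df.columns[0]
    spots = df[spot_col].astype(str).tolist()
    genes = [str(c) for c in df.columns[1:]]
    return spots, genes, df.iloc[:, 1:].to_numpy(dtype=float)


def read_slice(counts_path, coords_path, labels_path, donor_id="donor0", slice_id="slice0") -> SpatialSlice:
    """Assemble one slice from counts, coordinates and labels files.

    The coordinate table defines the set of spots.  Spots present in the
    coordinates but absent from the counts (or without a usable label) are
    flagged missing (``r = 0``) with a zero placeholder expression row.
    Counts may be a delimited spots x genes table (first column spot ids) or
    a MatrixMarket ``.mtx`` with companion ``features``/``genes`` and
    ``barcodes`` files.
    """
    from .spatial_graph import read_coords

    spot_ids, coords = read_coords(coords_path)
    count_spots, gene_names, counts = _read_counts(counts_path)
    count_index = {s: i for i, s in enumerate(count_spots)}
    if not set(spot_ids) & set(count_spots):
        raise ValueError("no spot_id overlap between coordinates and counts")

    labels = _read_table(labels_path)
    if "spot_id" not in labels.columns:
        raise ValueError("labels table needs a spot_id column")
    label_col = [c for c in labels.columns if c != "spot_id"][0]
    lab = dict(zip(labels["spot_id"].astype(str), labels[label_col]))
    bad = [v for v in lab.values() if not (pd.isna(v) or v in (0, 1))]
    if bad:
        raise ValueError(f"labels must be binary 0/1 (or absent); found values {sorted(set(bad))}")

    n, d = len(spot_ids), len(gene_names)
    X = np.zeros((n, d))
    y = np.full(n, np.nan)
    r = np.zeros(n, dtype=int)
    for i, sid in enumerate(spot_ids):
        j = count_index.get(sid)
        li = lab.get(sid)
        if j is not None and li is not None and not pd.isna(li):
            X[i] = counts[j]
            y[i] = float(li)
            r[i] = 1
    return SpatialSlice(donor_id, slice_id, coords, X, gene_names, y, r, spot_ids=spot_ids)


def write_slice(slc: SpatialSlice, out_dir, prefix=""):
    """Write a slice as the delimited tables ``read_slice`` accepts.

    Counts rows are written for observed spots only, so missing spots
    round-trip as missing.  Returns the three file paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    obs = slc.observed
    counts = pd.DataFrame(slc.X[obs], columns=slc.gene_names)
    counts.insert(0, "spot_id", [s for s, o in zip(slc.spot_ids, obs) if o])
    coords = pd.DataFrame({"spot_id": slc.spot_ids, "x": slc.coords[:, 0], "y": slc.coords[:, 1]})
    labels = pd.DataFrame(
        {"spot_id": [s for s, o in zip(slc.spot_ids, obs) if o], "label": slc.y[obs].astype(int)}
    )
    paths = (
        out_dir / f"{prefix}counts.tsv",
        out_dir / f"{prefix}coords.tsv",
        out_dir / f"{prefix}labels.tsv",
    )
    counts.to_csv(paths[0], sep="\t", index=False)
    coords.to_csv(paths[1], sep="\t", index=False)
    labels.to_csv(paths[2], sep="\t", index=False)
    return paths


def write_study(study: StudyDataset, out_dir):
    """Write every slice plus a manifest table; inverse of :func:`read_study`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, slc in enumerate(study.slices):
        prefix = f"s{k}_"
        write_slice(slc, out_dir, prefix=prefix)
        rows.append({"prefix": prefix, "donor_id": slc.donor_id, "slice_id": slc.slice_id})
    pd.DataFrame(rows).to_csv(out_dir / "slices.tsv", sep="\t", index=False)
    return out_dir


def read_study(data_dir) -> StudyDataset:
    data_dir = Path(data_dir)
    manifest = pd.read_csv(data_dir / "slices.tsv", sep="\t")
    slices = []
    for row in manifest.itertuples(index=False):
        p = row.prefix
        slices.append(
            read_slice(
                data_dir / f"{p}counts.tsv",
                data_dir / f"{p}coords.tsv",
                data_dir / f"{p}labels.tsv",
                donor_id=str(row.donor_id),
                slice_id=str(row.slice_id),
            )
        )
    return StudyDataset(slices=slices)


def filter_genes(study: StudyDataset, min_total: int = 300) -> StudyDataset:
    """Drop low-count genes and intersect gene sets across slices.

    Per slice, genes whose total count (over observed spots) is below
    ``min_total`` are removed (a total of exactly ``min_total`` is kept).
    Surviving gene sets are then intersected within each donor, and finally
    across donors so a joint fit sees one common gene list.  Expects raw
    counts; apply before :func:`log_transform`.
    """
    per_slice_keep = []
    for slc in study.slices:
        totals = slc.X[slc.observed].sum(axis=0)
        keep = {g for g, t in zip(slc.gene_names, totals) if t >= min_total}
        per_slice_keep.append(keep)

    donor_sets = {}
    for slc, keep in zip(study.slices, per_slice_keep):
        donor_sets[slc.donor_id] = donor_sets.get(slc.donor_id, keep) & keep
    common = None
    for s in donor_sets.values():
        common = s if common is None else common & s
    ordered = [g for g in study.slices[0].gene_names if g in common]
    if not ordered:
        raise ValueError(f"no genes survive filtering at min_total={min_total}")

    new_slices = []
    for slc in study.slices:
        idx = [slc.gene_names.index(g) for g in ordered]
        new_slices.append(replace(slc, X=slc.X[:, idx], gene_names=list(ordered)))
    return StudyDataset(slices=new_slices, truth=study.truth)


def log_transform(study: StudyDataset) -> StudyDataset:
    """Replace every count ``x`` by ``ln(x + 1)``."""
    new_slices = []
    for slc in study.slices:
        if np.any(slc.X[slc.observed] < 0):
            raise ValueError("log transform expects nonnegative counts")
        new_slices.append(replace(slc, X=np.log1p(slc.X)))
    return StudyDataset(slices=new_slices, truth=study.truth)
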