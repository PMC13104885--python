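"""Readers and writers for the pipeline's on-disk formats.

Counts travel as 10x-style Matrix-Market triplet directories (matrix.mtx
with features as rows and barcodes as columns, features.tsv, barcodes.tsv)
plus a per-nucleus metadata TSV; pathway catalogs as GMT (one pathway per
line: id, category as the description field, then genes, tab-separated);
ligand-receptor tables as CSV with a ``ligand,receptor,pathway`` header;
Raman spectra as two-column TSV (wavenumber_cm-1, intensity; ``#`` comment
lines allowed); ground truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .simulate import GroundTruth, Pathway, PathwayCatalog
from .spectral import RamanSpectrum

__all__ = [
    "write_population",
    "read_population",
    "write_gmt",
    "read_gmt",
    "write_lr_table",
    "read_lr_table",
    "write_spectrum",
    "read_spectrum",
    "write_ground_truth",
    "read_ground_truth",
]

_META_COLS = ("tissue", "condition", "cell_type", "cluster")


def write_population(adata: ad.AnnData, outdir: str | Path) -> Path:
    """Write counts as matrix.mtx + features.tsv + barcodes.tsv + meta.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts = adata.layers.get("counts", adata.X)
    mat = sparse.csr_matrix(counts) if not sparse.issparse(counts) else counts
    spio.mmwrite(outdir / "matrix.mtx", mat.T.astype(int))  # features x barcodes
    pd.Series(adata.var_names).to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)
    meta = adata.obs[[c for c in _META_COLS if c in adata.obs.columns]]
    meta.to_csv(outdir / "meta.tsv", sep="\t", index_label="barcode")
    return outdir


def read_population(indir: str | Path) -> ad.AnnData:
    """Read a triplet directory written by :func:`write_population`."""
    indir = Path(indir)
    mat = sparse.csr_matrix(spio.mmread(indir / "matrix.mtx")).T.astype(np.int32)
    features = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    adata = ad.AnnData(
        X=mat.copy(),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(features, name="gene")),
    )
    adata.layers["counts"] = mat
    meta_path = indir / "meta.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", index_col="barcode")
        adata.obs = adata.obs.join(meta)
    return adata


def write_gmt(catalog: PathwayCatalog, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for p in catalog:
            fh.write("\t".join([p.pathway_id, p.category, *p.genes]) + "\n")
    return path


def read_gmt(path: str | Path) -> PathwayCatalog:
    pathways = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (need id, description, >=1 gene): {line!r}")
        pathways.append(
            Pathway(pathway_id=fields[0], name=fields[0], category=fields[1], genes=tuple(fields[2:]))
        )
    return PathwayCatalog(pathways)


def write_lr_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table[["ligand", "receptor", "pathway"]].to_csv(path, index=False)
    return path


def read_lr_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = {"ligand", "receptor", "pathway"} - set(table.columns)
    if missing:
        raise ValueError(f"L-R table missing columns: {sorted(missing)}")
    return table


def write_spectrum(spectrum: RamanSpectrum, path: str | Path, header: bool = True) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        if header:
            fh.write("# wavenumber_cm-1\tintensity\n")
        for nu, inten in zip(spectrum.wavenumbers, spectrum.intensities):
            fh.write(f"{nu:.6g}\t{inten:.10g}\n")
    return path


def read_spectrum(path: str | Path) -> RamanSpectrum:
    data = np.loadtxt(path, comments="#")
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError("spectrum files must have exactly two columns")
    return RamanSpectrum(data[:, 0], data[:, 1])


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(truth.to_dict(), indent=1))
    return path


def read_ground_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
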