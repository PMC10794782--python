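"""Readers and writers for the package's plain-text interchange formats.

Datasets travel as Matrix Market trios (matrix.mtx, genes.tsv, barcodes.tsv)
with an optional metadata.tsv; cell-state matrices as TSV plus a JSON
sidecar of state metadata; labels and curves as TSV; configs as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .integration import CellStateMatrix


def write_dataset_mtx(adata: ad.AnnData, outdir: str | Path) -> None:
    """Write one dataset as matrix.mtx (cells × genes) + genes/barcodes TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    x = adata.X
    x = sp.csr_matrix(x) if not sp.issparse(x) else x
    scipy.io.mmwrite(outdir / "matrix.mtx", x)
    pd.Series(adata.var_names).to_csv(
        outdir / "genes.tsv", sep="\t", index=False, header=False
    )
    pd.Series(adata.obs_names).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    if adata.obs.shape[1]:
        adata.obs.to_csv(outdir / "metadata.tsv", sep="\t")


def read_dataset_mtx(indir: str | Path) -> ad.AnnData:
    """Read a matrix.mtx + genes.tsv + barcodes.tsv (+ metadata.tsv) trio."""
    indir = Path(indir)
    x = scipy.io.mmread(indir / "matrix.mtx").tocsr()
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    obs = pd.DataFrame(index=barcodes)
    meta_path = indir / "metadata.tsv"
    if meta_path.exists():
        obs = pd.read_csv(meta_path, sep="\t", index_col=0)
        obs.index = obs.index.astype(str)
    return ad.AnnData(x, obs=obs, var=pd.DataFrame(index=genes))


def read_dense_matrix(path: str | Path) -> ad.AnnData:
    """Read a dense cells × genes CSV/TSV (cell ids in the first column)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ad.AnnData(
        df.to_numpy(dtype=np.float64),
        obs=pd.DataFrame(index=df.index.astype(str)),
        var=pd.DataFrame(index=df.columns.astype(str)),
    )


def write_state_matrix(m: CellStateMatrix, path: str | Path) -> None:
    """Cell-state matrix as TSV plus a <path>.meta.json metadata sidecar."""
    path = Path(path)
    m.values.to_csv(path, sep="\t")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(m.state_meta.replace({np.nan: None}).to_json(orient="index"))


def read_state_matrix(path: str | Path) -> CellStateMatrix:
    path = Path(path)
    values = pd.read_csv(path, sep="\t", index_col=0)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        meta = pd.read_json(sidecar, orient="index")
        meta.index = meta.index.astype(str)
        meta = meta.loc[values.index.astype(str)]
    else:
        meta = pd.DataFrame(index=values.index)
    values.index = values.index.astype(str)
    meta.index = values.index
    return CellStateMatrix(values, meta)


def write_labels(labels: pd.Series, path: str | Path) -> None:
    labels.rename("profile_id").rename_axis("state_id").to_csv(path, sep="\t")


def read_labels(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].astype(int)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def read_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def write_yaml(obj: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))
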