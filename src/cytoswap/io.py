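"""Readers and writers for the pipeline's tabular and image formats.

Tables are plain TSV/CSV through pandas; images are 16-bit grayscale TIFF or
PNG through imageio; every simulation output can carry a JSON sidecar with
the seed and parameters that produced it.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .genetics import LocusAllele, Plasmid, Medium, Spore, Tetrad, media_viability

__all__ = [
    "write_tsv",
    "read_tsv",
    "read_growth_csv",
    "write_growth_csv",
    "write_image",
    "read_image",
    "write_sidecar",
    "tetrads_to_frame",
    "frame_to_tetrads",
]

_TETRAD_COLS = ["tetrad_id", "spore_id", "locus_allele", "plasmid",
                "complements", "viable", "MAT", "LYS2", "MET15"]


def write_tsv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_tsv(path, required: Sequence[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if required:
        missing = set(required) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_growth_csv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_growth_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"strain", "medium", "temperature_c", "replicate", "time_min", "od600"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_image(image: np.ndarray, path) -> Path:
    """Write a float [0, 1] image as 16-bit grayscale TIFF or PNG."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(path, (arr * 65535).round().astype(np.uint16))
    return path


def read_image(path) -> np.ndarray:
    """Read an 8- or 16-bit grayscale image back to float [0, 1]."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:  # drop a redundant channel axis if present
        arr = arr[..., 0]
    scale = 65535.0 if arr.dtype == np.uint16 else float(np.iinfo(arr.dtype).max)
    return arr.astype(float) / scale


def write_sidecar(path, seed: int, params: dict) -> Path:
    """JSON sidecar recording the seed and parameters next to an output."""
    path = Path(str(path) + ".json")
    path.write_text(json.dumps({"seed": seed, "params": params}, indent=2, default=str))
    return path


def tetrads_to_frame(tetrads: Sequence[Tetrad]) -> pd.DataFrame:
    rows = []
    for ti, t in enumerate(tetrads):
        for si, s in enumerate(t.spores):
            rows.append(
                dict(
                    tetrad_id=ti,
                    spore_id=si,
                    locus_allele=s.locus_allele.value,
                    plasmid=s.plasmid.value,
                    complements=s.human_gene_complements,
                    viable=media_viability(s, Medium.YPD),
                    MAT=s.aux_markers.get("MAT", ""),
                    LYS2=s.aux_markers.get("LYS2", ""),
                    MET15=s.aux_markers.get("MET15", ""),
                )
            )
    return pd.DataFrame(rows, columns=_TETRAD_COLS)


def frame_to_tetrads(df: pd.DataFrame) -> list[Tetrad]:
    """Rebuild tetrads from the TSV layout written by :func:`tetrads_to_frame`.

    The ``viable`` column reflects observed growth on YPD; it is folded back
    into the intrinsic-viability flag (a spore recorded dead is treated as
    intrinsically dead, since plate records cannot distinguish the cause).
    """
    missing = set(_TETRAD_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"tetrad table missing columns: {sorted(missing)}")
    tetrads = []
    for _, g in df.groupby("tetrad_id", sort=True):
        g = g.sort_values("spore_id")
        spores = []
        for _, r in g.iterrows():
            spores.append(
                Spore(
                    locus_allele=LocusAllele(r["locus_allele"]),
                    plasmid=Plasmid(r["plasmid"]),
                    human_gene_complements=bool(r["complements"]),
                    intrinsically_viable=bool(r["viable"]),
                    aux_markers={m: r[m] for m in ("MAT", "LYS2", "MET15")},
                )
            )
        tetrads.append(Tetrad(tuple(spores)))
    return tetrads
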