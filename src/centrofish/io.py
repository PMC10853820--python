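"""Shared I/O: OME-TIFF stacks with pixel-size metadata, detection and
quantification CSV tables, ground-truth CSV, FASTA transcripts.
"""

from __future__ import annotations

import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .config import CHANNELS
from .quantify import QuantRecord
from .simulate import GroundTruth

#: Fixed, documented column order of the QuantRecord CSV.
QUANT_COLUMNS = (
    ["cell_id", "centrosome_id", "timepoint", "stage_label", "flagged"]
    + [f"{c}_{kind}" for c in CHANNELS
       for kind in ("disk_total", "background_total", "enrichment",
                    "peak_position")]
)


@dataclass
class ImageStack:
    """A channel-labelled image stack with physical pixel size."""

    data: np.ndarray              # (C, Y, X)
    channel_names: list[str]
    pixel_size: float             # µm / pixel

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channel_names.index(name)]

    def channels(self) -> dict[str, np.ndarray]:
        return {n: self.data[i] for i, n in enumerate(self.channel_names)}


def write_stack(path, data: np.ndarray, pixel_size: float,
                channel_names=CHANNELS) -> None:
    """Write a (C, Y, X) stack as OME-TIFF with labelled channels and
    PhysicalSizeX/Y set to ``pixel_size`` (µm)."""
    data = np.asarray(data, dtype=np.float32)
    if data.ndim != 3 or data.shape[0] != len(channel_names):
        raise ValueError("data must be (C, Y, X) matching channel_names")
    tifffile.imwrite(
        path, data, ome=True,
        metadata={
            "axes": "CYX",
            "PhysicalSizeX": pixel_size, "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": pixel_size, "PhysicalSizeYUnit": "µm",
            "Channel": {"Name": list(channel_names)},
        },
    )


def _parse_ome(ome_xml: str) -> tuple[float | None, list[str]]:
    """PhysicalSizeX and channel names from OME-XML (namespace-agnostic)."""
    root = ET.fromstring(ome_xml)
    pixel_size = None
    names: list[str] = []
    for el in root.iter():
        tag = el.tag.rsplit("}", 1)[-1]
        if tag == "Pixels" and pixel_size is None:
            if "PhysicalSizeX" in el.attrib:
                pixel_size = float(el.attrib["PhysicalSizeX"])
        elif tag == "Channel":
            names.append(el.attrib.get("Name", f"C{len(names)}"))
    return pixel_size, names


def read_stack(path, pixel_size: float | None = None,
               channel_names=None) -> ImageStack:
    """Read a TIFF/OME-TIFF stack as channel-labelled planes.

    Pixel size and channel names come from OME metadata; either may be
    overridden.  A plain TIFF without metadata requires an explicit
    ``pixel_size`` (error otherwise) and falls back to generic channel
    names with a warning.
    """
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta_px, meta_names = (None, [])
        if tif.ome_metadata:
            meta_px, meta_names = _parse_ome(tif.ome_metadata)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"{path}: ambiguous axis order for {data.shape}; "
                         "expected (C, Y, X)")
    px = pixel_size if pixel_size is not None else meta_px
    if px is None:
        raise ValueError(f"{path}: no pixel-size metadata and no override "
                         "configured")
    names = list(channel_names) if channel_names is not None else meta_names
    if len(names) != data.shape[0]:
        if channel_names is not None:
            raise ValueError(f"{path}: {data.shape[0]} planes but "
                             f"{len(names)} channel names")
        warnings.warn(f"{path}: missing channel names; using C0..C{data.shape[0]-1}")
        names = [f"C{i}" for i in range(data.shape[0])]
    return ImageStack(data=np.asarray(data, dtype=float),
                      channel_names=names, pixel_size=float(px))


def ground_truth_frame(truths: list[GroundTruth]) -> pd.DataFrame:
    """One row per simulated object (centrosome or RNA spot)."""
    rows = []
    for gt in truths:
        tp = gt.timepoint if gt.timepoint is not None else ""
        for i, (c, a) in enumerate(zip(gt.centrosome_centers, gt.spindle_axes)):
            rows.append({"type": "centrosome", "x_um": c[1], "y_um": c[0],
                         "channel": "marker", "timepoint": tp,
                         "cell_id": gt.cell_id, "centrosome_id": i,
                         "axis_x": a[1], "axis_y": a[0]})
        for p, cid in zip(gt.rna_positions, gt.rna_centrosome_ids):
            rows.append({"type": "rna", "x_um": p[1], "y_um": p[0],
                         "channel": "rna", "timepoint": tp,
                         "cell_id": gt.cell_id, "centrosome_id": int(cid),
                         "axis_x": "", "axis_y": ""})
    return pd.DataFrame(rows)


def quant_frame(records: list[QuantRecord]) -> pd.DataFrame:
    """QuantRecords as a table in the fixed QUANT_COLUMNS order."""
    rows = []
    for r in records:
        row = {"cell_id": r.cell_id, "centrosome_id": r.centrosome_id,
               "timepoint": r.timepoint, "stage_label": r.stage_label,
               "flagged": r.flagged}
        for c in CHANNELS:
            row[f"{c}_disk_total"] = r.disk_total.get(c)
            row[f"{c}_background_total"] = r.background_total.get(c)
            row[f"{c}_enrichment"] = r.enrichment.get(c)
            row[f"{c}_peak_position"] = r.peak_position.get(c)
        rows.append(row)
    return pd.DataFrame(rows, columns=QUANT_COLUMNS)


def records_from_frame(df: pd.DataFrame) -> list[QuantRecord]:
    """Inverse of :func:`quant_frame`."""
    records = []
    for _, row in df.iterrows():
        tp = row["timepoint"]
        rec = QuantRecord(
            cell_id=int(row["cell_id"]),
            centrosome_id=int(row["centrosome_id"]),
            timepoint=None if pd.isna(tp) else float(tp),
            stage_label=str(row["stage_label"]),
            flagged=bool(row["flagged"]),
        )
        for c in CHANNELS:
            if pd.notna(row.get(f"{c}_enrichment")):
                rec.disk_total[c] = float(row[f"{c}_disk_total"])
                rec.background_total[c] = float(row[f"{c}_background_total"])
                rec.enrichment[c] = float(row[f"{c}_enrichment"])
                rec.peak_position[c] = float(row[f"{c}_peak_position"])
        records.append(rec)
    return records


def read_fasta(path) -> dict[str, str]:
    """Transcript FASTA → {id: sequence} (Biopython)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_probe_outputs(probe_set, out_dir, name: str = "probes") -> None:
    """Write probe FASTA and the TSV (start, length, gc, probe_seq, oligo_seq)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = [{"start": p.start, "length": p.length, "gc": round(p.gc, 4),
             "probe_seq": p.sequence, "oligo_seq": o}
            for p, o in zip(probe_set.probes, probe_set.oligos)]
    pd.DataFrame(rows).to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
    with open(out_dir / f"{name}.fasta", "w") as fh:
        for i, o in enumerate(probe_set.oligos):
            fh.write(f">{name}_{i:02d}\n{o}\n")
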