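"""File I/O: PLINK1 bed/bim/fam, TSV tables, JSON summaries and run manifests.

Coordinates in all TSV outputs are 1-based inclusive; BED-style exclusion
region inputs are 0-based half-open.  The PLINK1 binary codec is SNP-major
(magic bytes 0x6c 0x1b 0x01) with 2-bit genotype codes packed four
individuals per byte from the least-significant bit pair:
00 = homozygous A1 (dosage 2 of the counted allele), 10 = heterozygous,
11 = homozygous A2 (dosage 0), 01 = missing.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel, validate_variant_table

__all__ = ["read_genotypes", "write_genotypes", "read_exclude_bed",
           "write_truth", "read_truth", "write_manifest"]

_BED_MAGIC = bytes((0x6C, 0x1B, 0x01))
# 2-bit code per dosage: index 0..2 → code; missing handled separately
_DOSAGE_TO_CODE = np.array([3, 2, 0], dtype=np.uint8)   # 0→11, 1→10, 2→00
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)


def write_genotypes(panel: GenotypePanel, variants: pd.DataFrame, prefix: str | Path,
                    write_variant_table: bool = True) -> None:
    """Write a panel as PLINK1 ``prefix.bed/.bim/.fam`` (SNP-major).

    The full variant table (ancestry and any annotation columns) goes to
    ``prefix.variants.tsv`` so that a round trip preserves metadata the bim
    format cannot carry.
    """
    validate_variant_table(variants)
    prefix = Path(prefix)
    n, m = panel.n_individuals, panel.n_variants
    if len(variants) != m:
        raise ValueError("variant table length must match panel width")

    d = panel.dosages
    codes = np.where(d == MISSING, np.uint8(1), _DOSAGE_TO_CODE[np.clip(d, 0, 2)])
    pad = (-n) % 4
    if pad:
        codes = np.vstack([codes, np.zeros((pad, m), np.uint8)])
    quads = codes.T.reshape(m, -1, 4).astype(np.uint8)
    shifts = np.array([0, 2, 4, 6], np.uint8)
    body = (quads << shifts).sum(axis=2, dtype=np.uint8).astype(np.uint8)
    with open(Path(str(prefix) + ".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(body.tobytes())

    bim = pd.DataFrame({
        "chrom": variants["chrom"], "id": variants["variant_id"],
        "cm": 0, "pos": variants["pos_bp"], "a1": "A", "a2": "C",
    })
    bim.to_csv(Path(str(prefix) + ".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame({
        "fid": [f"F{i}" for i in range(n)], "iid": [f"I{i}" for i in range(n)],
        "father": 0, "mother": 0, "sex": 0, "pheno": -9,
    })
    fam.to_csv(Path(str(prefix) + ".fam"), sep="\t", header=False, index=False)
    if write_variant_table:
        variants.to_csv(str(prefix) + ".variants.tsv", sep="\t", index=False)


def read_genotypes(prefix: str | Path) -> tuple[GenotypePanel, pd.DataFrame]:
    """Read PLINK1 ``prefix.bed/.bim/.fam`` back into a panel + variant table.

    If ``prefix.variants.tsv`` (written by :func:`write_genotypes`) is present
    its columns override/extend the bim-derived metadata, restoring ancestry
    labels and annotations.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(Path(str(prefix) + ".bim"), sep=r"\s+", header=None,
                      names=["chrom", "id", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str})
    fam = pd.read_csv(Path(str(prefix) + ".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"])
    n, m = len(fam), len(bim)
    raw = Path(str(prefix) + ".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(
            f"not a SNP-major PLINK1 bed file: magic bytes {raw[:3]!r}")
    bytes_per_variant = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if len(body) != m * bytes_per_variant:
        raise ValueError(
            f"truncated bed file: expected {m * bytes_per_variant} body bytes, "
            f"found {len(body)}")
    quads = body.reshape(m, bytes_per_variant)
    shifts = np.array([0, 2, 4, 6], np.uint8)
    codes = ((quads[:, :, None] >> shifts) & 0x3).reshape(m, -1)[:, :n]
    dosages = _CODE_TO_DOSAGE[codes].T.copy()

    sidecar = Path(str(prefix) + ".variants.tsv")
    if sidecar.exists():
        variants = pd.read_csv(sidecar, sep="\t", dtype={"chrom": str})
    else:
        panel_tmp = GenotypePanel(dosages)
        p = panel_tmp.allele_freqs()
        variants = pd.DataFrame({
            "chrom": bim["chrom"], "pos_bp": bim["pos"], "variant_id": bim["id"],
            "ancestry": "MH", "allele_freq": p, "maf": np.minimum(p, 1 - p),
        })
    return GenotypePanel(dosages), variants


def read_exclude_bed(path: str | Path) -> pd.DataFrame:
    """Read a 3-column BED (chrom, start, end; 0-based half-open)."""
    return pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                       names=["chrom", "start", "end"], dtype={0: str})


def write_truth(truth, path: str | Path) -> None:
    payload = {
        "causal_ids": list(map(str, truth.causal_ids)),
        "beta": [float(b) for b in truth.beta],
        "true_h2": truth.true_h2,
        "true_h2_nim": truth.true_h2_nim,
        "seed": truth.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path: str | Path, y: np.ndarray | None = None):
    from .synthio import PhenotypeTruth
    payload = json.loads(Path(path).read_text())
    return PhenotypeTruth(
        y=np.asarray(y) if y is not None else np.zeros(0),
        causal_ids=np.array(payload["causal_ids"]),
        beta=np.array(payload["beta"]),
        true_h2=payload["true_h2"], true_h2_nim=payload["true_h2_nim"],
        seed=payload.get("seed"))


def write_manifest(out_dir: str | Path, config: dict, seed: int | None) -> Path:
    """Write a reproducibility manifest (config hash, seed, versions)."""
    from . import __version__
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": seed,
        "versions": {
            "nimkit": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
    }
    out = Path(out_dir) / "manifest.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(manifest, indent=1, default=str))
    return out
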