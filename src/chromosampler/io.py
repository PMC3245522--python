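"""Readers and writers for dataset, ensemble and report formats.

Formats are plain text: fragments TSV (id, chrom, start, end; 0-based
half-open), 5C pairs TSV (frag_i, frag_j, if_value, sigma; 1-based ids),
dense Hi-C count matrix TSV with ``chrom:start-end`` headers, and PDB
output with one CA pseudo-atom per fragment.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .core import (Conformation, FragmentMap, InteractionDataset, TECH_5C,
                   TECH_HIC)
from .sampler import Ensemble

__all__ = [
    "read_fragments",
    "write_fragments",
    "read_pairs",
    "write_pairs",
    "read_hic_matrix",
    "write_hic_matrix",
    "read_dataset",
    "write_dataset",
    "write_ensemble_pdb",
    "read_ensemble_pdb",
    "write_run_record",
]

PDB_COORD_MAX = 999.999  # widest signed value fitting the fixed 8.3 PDB field
NM_TO_ANGSTROM = 10.0


class FormatError(ValueError):
    """A file failed to parse or validate; the message names the location."""


def read_fragments(path) -> FragmentMap:
    df = pd.read_csv(path, sep="\t")
    required = ["id", "chrom", "start", "end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    for col in ("id", "start", "end"):
        if not pd.api.types.is_integer_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            loc = f"line {bad[0] + 2}" if len(bad) else f"column {col}"
            raise FormatError(f"{path}: non-integer value in {col} ({loc})")
    df = df.sort_values("id")
    ids = df["id"].to_numpy()
    if not np.array_equal(ids, np.arange(1, len(ids) + 1)):
        raise FormatError(f"{path}: fragment ids must be 1..n without gaps")
    return FragmentMap(df["chrom"].to_numpy(dtype=object),
                       df["start"].to_numpy(), df["end"].to_numpy())


def write_fragments(fmap: FragmentMap, path) -> None:
    pd.DataFrame({"id": np.arange(1, fmap.n + 1), "chrom": fmap.chroms,
                  "start": fmap.starts, "end": fmap.ends}
                 ).to_csv(path, sep="\t", index=False)


def read_pairs(path, fmap: FragmentMap) -> InteractionDataset:
    df = pd.read_csv(path, sep="\t")
    required = ["frag_i", "frag_j", "if_value", "sigma"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    for col in required:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna()]
        if len(bad):
            raise FormatError(
                f"{path}: non-numeric {col} at line {bad[0] + 2}")
    fi = df["frag_i"].to_numpy(np.int64)
    fj = df["frag_j"].to_numpy(np.int64)
    for col, arr in (("frag_i", fi), ("frag_j", fj)):
        bad = np.flatnonzero((arr < 1) | (arr > fmap.n))
        if len(bad):
            raise FormatError(
                f"{path}: line {bad[0] + 2}: unknown fragment id "
                f"{arr[bad[0]]} (map has {fmap.n} fragments)")
    lo, hi = np.minimum(fi, fj), np.maximum(fi, fj)
    if np.any(lo == hi):
        bad = int(np.flatnonzero(lo == hi)[0])
        raise FormatError(f"{path}: line {bad + 2}: self-pair {lo[bad]}")
    keys = lo * (fmap.n + 1) + hi
    uniq, counts = np.unique(keys, return_counts=True)
    if np.any(counts > 1):
        dup = uniq[counts > 1][0]
        line = int(np.flatnonzero(keys == dup)[1])
        raise FormatError(
            f"{path}: line {line + 2}: duplicate pair "
            f"({dup // (fmap.n + 1)}, {dup % (fmap.n + 1)})")
    return InteractionDataset(fmap, TECH_5C, lo - 1, hi - 1,
                              df["if_value"].to_numpy(float),
                              df["sigma"].to_numpy(float))


def write_pairs(data: InteractionDataset, path) -> None:
    if data.technology != TECH_5C:
        raise ValueError("write_pairs expects a 5C dataset")
    pd.DataFrame({"frag_i": data.pair_i + 1, "frag_j": data.pair_j + 1,
                  "if_value": data.values, "sigma": data.sigmas}
                 ).to_csv(path, sep="\t", index=False)


def _bin_label(chrom, start, end) -> str:
    return f"{chrom}:{start}-{end}"


def write_hic_matrix(data: InteractionDataset, path) -> None:
    """Dense symmetric count matrix; unmeasured pairs written as NaN."""
    if data.technology != TECH_HIC:
        raise ValueError("write_hic_matrix expects a Hi-C dataset")
    n = data.n_fragments
    mat = np.full((n, n), np.nan)
    mat[data.pair_i, data.pair_j] = data.values
    mat[data.pair_j, data.pair_i] = data.values
    np.fill_diagonal(mat, 0.0)
    fm = data.fragment_map
    labels = [_bin_label(fm.chroms[i], fm.starts[i], fm.ends[i])
              for i in range(n)]
    pd.DataFrame(mat, index=labels, columns=labels).to_csv(path, sep="\t")


def read_hic_matrix(path) -> InteractionDataset:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise FormatError(f"{path}: matrix is not square")
    chroms, starts, ends = [], [], []
    for lab in df.columns:
        try:
            chrom, rng = lab.rsplit(":", 1)
            s, e = rng.split("-")
            starts.append(int(s))
            ends.append(int(e))
            chroms.append(chrom)
        except ValueError as exc:
            raise FormatError(
                f"{path}: malformed bin header {lab!r} "
                "(expected chrom:start-end)") from exc
    fmap = FragmentMap(np.array(chroms, dtype=object), starts, ends)
    mat = df.to_numpy(dtype=float)
    if not np.allclose(mat, mat.T, equal_nan=True):
        raise FormatError(f"{path}: count matrix is not symmetric")
    iu, ju = np.triu_indices(fmap.n, k=1)
    vals = mat[iu, ju]
    keep = ~np.isnan(vals)  # NaN cells = unmeasured pairs
    return InteractionDataset(fmap, TECH_HIC, iu[keep], ju[keep], vals[keep])


def read_dataset(fragments_path=None, pairs_path=None, matrix_path=None,
                 technology: Optional[str] = None) -> InteractionDataset:
    """Load a dataset: fragments + pairs (5C) or a count matrix (Hi-C)."""
    if matrix_path is not None:
        if technology not in (None, TECH_HIC):
            raise ValueError("a matrix file implies Hi-C")
        return read_hic_matrix(matrix_path)
    if fragments_path is None or pairs_path is None:
        raise ValueError("5C input needs both a fragments and a pairs file")
    return read_pairs(pairs_path, read_fragments(fragments_path))


def write_dataset(data: InteractionDataset, out_dir,
                  prefix: str = "dataset") -> List[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if data.technology == TECH_5C:
        frag = out_dir / f"{prefix}.fragments.tsv"
        pairs = out_dir / f"{prefix}.pairs.tsv"
        write_fragments(data.fragment_map, frag)
        write_pairs(data, pairs)
        return [frag, pairs]
    mat = out_dir / f"{prefix}.matrix.tsv"
    write_hic_matrix(data, mat)
    return [mat]


def _pdb_scale(points: np.ndarray) -> float:
    """Scale factor applied before writing: nm -> Angstrom, shrunk if the
    coordinates would overflow the fixed-width field."""
    m = float(np.abs(points).max())
    scale = NM_TO_ANGSTROM
    if m * scale > PDB_COORD_MAX:
        scale = PDB_COORD_MAX / m
    return scale


def write_conformation_pdb(points: np.ndarray, path, *,
                           log_posterior: Optional[float] = None) -> float:
    """One CA pseudo-atom per fragment, chain A, residues 1..n.

    Returns the scale factor recorded in the REMARK records; divide the
    file's coordinates by it to recover model units.
    """
    points = np.asarray(points, float)
    scale = _pdb_scale(points)
    with open(path, "w") as fh:
        fh.write(f"REMARK 250 COORDINATE SCALE FACTOR {scale:.9e}\n")
        if log_posterior is not None:
            fh.write(f"REMARK 250 LOG POSTERIOR {log_posterior:.6f}\n")
        for i, (x, y, z) in enumerate(points * scale, start=1):
            fh.write(
                f"ATOM  {i:5d}  CA  CHR A{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n")
        fh.write("END\n")
    return scale


def read_conformation_pdb(path) -> Tuple[Conformation, dict]:
    """Parse a PDB written by this package; rescales to model units."""
    coords = []
    meta = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("REMARK 250 COORDINATE SCALE FACTOR"):
                meta["scale"] = float(line.split()[-1])
            elif line.startswith("REMARK 250 LOG POSTERIOR"):
                meta["log_posterior"] = float(line.split()[-1])
            elif line.startswith(("ATOM", "HETATM")):
                coords.append([float(line[30:38]), float(line[38:46]),
                               float(line[46:54])])
    if not coords:
        raise FormatError(f"{path}: no atom records")
    scale = meta.get("scale", 1.0)
    return Conformation(np.asarray(coords) / scale), meta


def write_ensemble_pdb(ens: Ensemble, out_dir,
                       prefix: str = "structure") -> Path:
    """One PDB per member plus a manifest TSV; returns the manifest path."""
    if len(ens) == 0:
        raise ValueError("empty ensemble")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(len(ens)):
        name = f"{prefix}_{i:04d}.pdb"
        scale = write_conformation_pdb(
            ens.conformations[i], out_dir / name,
            log_posterior=float(ens.log_posteriors[i]))
        rows.append((name, int(ens.chain_ids[i]), int(ens.iterations[i]),
                     float(ens.log_posteriors[i]), scale))
    manifest = out_dir / f"{prefix}_manifest.tsv"
    pd.DataFrame(rows, columns=["file", "chain_id", "iteration",
                                "log_posterior", "scale"]
                 ).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_ensemble_pdb(manifest_path,
                      fragment_map: Optional[FragmentMap] = None) -> Ensemble:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, sep="\t")
    confs = []
    for name in df["file"]:
        conf, _ = read_conformation_pdb(manifest_path.parent / name)
        confs.append(conf.points)
    return Ensemble(np.stack(confs), df["log_posterior"].to_numpy(float),
                    df["chain_id"].to_numpy(np.int64),
                    df["iteration"].to_numpy(np.int64),
                    fragment_map=fragment_map)


def write_run_record(out_dir, config: dict, seed: Optional[int] = None) -> Path:
    """Reproducibility record: config, seed, package versions, config hash."""
    import chromosampler

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "config": config,
        "seed": seed,
        "versions": {
            "chromosampler": chromosampler.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    record["config_sha256"] = hashlib.sha256(blob).hexdigest()
    path = out_dir / "run_record.json"
    path.write_text(json.dumps(record, indent=2, sort_keys=True, default=str))
    return path
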