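"""Table formats and run manifests.

All tables are comma-separated UTF-8 with a header row.  Genotypes are
encoded ``WW`` (+/+) and ``WT`` (+/t); ``TT`` never appears in data because
t/t homozygotes die before birth.  The litters table has one row per pup;
the pedigree uses the conventional id/dam/sire core with empty parents for
founders.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .drive import WW, WT
from .popsim import LITTER_COLUMNS, PEDIGREE_COLUMNS

__all__ = [
    "LitterParseError",
    "read_litters",
    "write_litters",
    "read_pedigree",
    "write_pedigree",
    "write_manifest",
]

_VALID_GENOTYPES = {WW, WT}


class LitterParseError(ValueError):
    pass


def read_litters(path: str | Path) -> pd.DataFrame:
    """Read and validate a litters table (one row per pup)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != LITTER_COLUMNS:
        raise LitterParseError(
            f"{path}: expected columns {LITTER_COLUMNS}, got {list(df.columns)}"
        )
    for col in ("mother_genotype", "pup_genotype"):
        bad = df.index[~df[col].isin(_VALID_GENOTYPES)]
        if len(bad):
            rows = [int(i) + 2 for i in bad[:5]]  # 1-based, after header
            raise LitterParseError(
                f"{path}: invalid {col} values at rows {rows} "
                f"(allowed: {sorted(_VALID_GENOTYPES)}; t/t pups cannot be sampled alive)"
            )
    dup = df["pup_id"].duplicated()
    if dup.any():
        rows = [int(i) + 2 for i in df.index[dup][:5]]
        raise LitterParseError(f"{path}: duplicate pup_id at rows {rows}")
    consistent = df.groupby("litter_id")[["mother_id", "mother_genotype", "cohort"]].nunique()
    bad_litters = consistent.index[(consistent > 1).any(axis=1)]
    if len(bad_litters):
        raise LitterParseError(
            f"{path}: inconsistent mother/cohort within litters {list(bad_litters[:5])}"
        )
    df["cohort"] = df["cohort"].astype(int)
    return df


def write_litters(litters: pd.DataFrame, path: str | Path) -> None:
    litters.to_csv(path, index=False, columns=LITTER_COLUMNS, lineterminator="\n")


def read_pedigree(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != PEDIGREE_COLUMNS:
        raise LitterParseError(
            f"{path}: expected columns {PEDIGREE_COLUMNS}, got {list(df.columns)}"
        )
    bad = df.index[~df["genotype"].isin(_VALID_GENOTYPES)]
    if len(bad):
        rows = [int(i) + 2 for i in bad[:5]]
        raise LitterParseError(f"{path}: invalid genotype values at rows {rows}")
    dup = df["id"].duplicated()
    if dup.any():
        rows = [int(i) + 2 for i in df.index[dup][:5]]
        raise LitterParseError(f"{path}: duplicate id at rows {rows}")
    df["cohort"] = df["cohort"].astype(int)
    return df


def write_pedigree(pedigree: pd.DataFrame, path: str | Path) -> None:
    pedigree.to_csv(path, index=False, columns=PEDIGREE_COLUMNS, lineterminator="\n")


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_manifest(path: str | Path, config, seed: int, counts: dict[str, int]) -> dict:
    """Write a reproducibility manifest: config (and its hash), seed,
    library versions and per-stage row counts."""
    cfg = _jsonable(config)
    blob = json.dumps(cfg, sort_keys=True).encode()
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "row_counts": counts,
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
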