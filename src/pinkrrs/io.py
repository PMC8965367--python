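"""CSV readers/writers, YAML configuration, logging and seed management.

All tables are plain RFC-4180 CSV. The genotype table is wide: two allele
columns per locus (``<locus>.1``, ``<locus>.2``), blank cells meaning a
missing genotype (no half-calls). Panels are stored long: one row per
allele with its frequency.
"""

from __future__ import annotations

import hashlib
import logging
import sys
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .records import (
    SAMPLE_COLUMNS,
    Config,
    ConfigError,
    GenotypeSet,
    Locus,
    LocusPanel,
    SampleRecord,
    SchemaError,
    ValidationError,
)

__all__ = [
    "read_sample_table",
    "write_sample_table",
    "read_genotype_table",
    "write_genotype_table",
    "read_panel",
    "write_panel",
    "load_config",
    "save_config",
    "records_to_frame",
    "frame_to_records",
    "substream",
    "spawn_rng",
    "file_checksum",
    "get_logger",
]

PathLike = Union[str, Path]

_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False,
             "yes": True, "no": False}


def get_logger(name: str = "pinkrrs", logfile: Optional[PathLike] = None) -> logging.Logger:
    """Logger writing to stderr and optionally to a file."""
    logger = logging.getLogger(name)
    if not logger.handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        logger.addHandler(h)
        logger.setLevel(logging.INFO)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        logger.addHandler(fh)
    return logger


def substream(master_seed: int, name: str) -> np.random.SeedSequence:
    """Named, stable child seed sequence of a master seed.

    Stage names hash to fixed 32-bit keys so reordering stages does not
    shift any stream.
    """
    key = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "big")
    return np.random.SeedSequence([int(master_seed), key])


def spawn_rng(master_seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(substream(master_seed, name))


def file_checksum(path: PathLike) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------- samples


def _coerce_bool(v, default=False):
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return default
    s = str(v).strip().lower()
    if s in _BOOL_MAP:
        return _BOOL_MAP[s]
    raise ValidationError(f"unparseable boolean {v!r}")


def read_sample_table(path: PathLike) -> pd.DataFrame:
    """Read a carcass-survey sample table.

    Rows whose origin cannot be parsed are kept with ``origin='unknown'``
    (never dropped); row count is preserved. Missing mandatory columns
    raise :class:`SchemaError` naming the column.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "hatchery_code": str})
    mandatory = [c for c in SAMPLE_COLUMNS if c != "hatchery_code"]
    for col in mandatory:
        if col not in df.columns:
            raise SchemaError(f"sample table missing mandatory column {col!r}")
    if "hatchery_code" not in df.columns:
        df["hatchery_code"] = None
    out = df.copy()
    origin = df["origin"].astype("string").str.strip().str.lower()
    origin = origin.where(origin.isin(["hatchery", "natural"]), "unknown")
    origin = origin.fillna("unknown")
    out["origin"] = origin.astype(str)
    # fields with constrained values: report the offending line number
    for i, (lin, sex) in enumerate(zip(df["lineage"], df["sex"])):
        if str(lin) not in ("odd", "even"):
            raise ValidationError(f"line {i + 2}: unparseable lineage {lin!r}")
        if str(sex) not in ("F", "M", "unknown"):
            raise ValidationError(f"line {i + 2}: unparseable sex {sex!r}")
    out["year"] = out["year"].astype(int)
    out["sample_day"] = out["sample_day"].astype(int)
    out["length_mm"] = out["length_mm"].astype(float)
    out["distance_m"] = out["distance_m"].astype(float)
    out["intertidal"] = [_coerce_bool(v) for v in out["intertidal"]]
    out["genotyped"] = [_coerce_bool(v) for v in out["genotyped"]]
    out["hatchery_code"] = out["hatchery_code"].where(pd.notna(out["hatchery_code"]), None)
    # a hatchery origin with no code (or vice versa) is inconsistent input
    bad = (out["origin"] == "hatchery") != out["hatchery_code"].notna()
    if bad.any():
        # tolerate by synthesizing/clearing the code only when unambiguous
        out.loc[bad & (out["origin"] == "hatchery"), "hatchery_code"] = "UNK"
        out.loc[bad & (out["origin"] != "hatchery"), "hatchery_code"] = None
    return out[SAMPLE_COLUMNS]


def write_sample_table(df: pd.DataFrame, path: PathLike) -> None:
    df = df[SAMPLE_COLUMNS].copy()
    df.to_csv(path, index=False)


def records_to_frame(records: list[SampleRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records], columns=SAMPLE_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[SampleRecord]:
    recs = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        code = d.get("hatchery_code")
        if code is not None and (isinstance(code, float) and np.isnan(code)):
            code = None
        d["hatchery_code"] = code
        recs.append(SampleRecord(**d))
    return recs


# ------------------------------------------------------------------ panel


def write_panel(panel: LocusPanel, path: PathLike) -> None:
    rows = []
    for loc in panel.loci:
        for a, f in zip(loc.alleles, loc.freqs):
            rows.append({"locus_id": loc.locus_id, "kind": loc.kind,
                         "allele": a, "freq": f})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_panel(path: PathLike) -> LocusPanel:
    df = pd.read_csv(path, dtype={"locus_id": str, "allele": str})
    for col in ("locus_id", "kind", "allele", "freq"):
        if col not in df.columns:
            raise SchemaError(f"panel table missing mandatory column {col!r}")
    loci = []
    for locus_id, grp in df.groupby("locus_id", sort=False):
        loci.append(Locus(
            locus_id=str(locus_id),
            kind=str(grp["kind"].iloc[0]),
            alleles=[str(a) for a in grp["allele"]],
            freqs=grp["freq"].to_numpy(float),
        ))
    return LocusPanel(loci)


# -------------------------------------------------------------- genotypes


def write_genotype_table(genotypes: GenotypeSet, path: PathLike) -> None:
    panel = genotypes.panel
    data = {"sample_id": genotypes.sample_ids}
    for l, loc in enumerate(panel.loci):
        for k in (0, 1):
            col = []
            for i in range(len(genotypes)):
                a = genotypes.alleles[i, l, k]
                col.append("" if a < 0 else loc.alleles[a])
            data[f"{loc.locus_id}.{k + 1}"] = col
    pd.DataFrame(data).to_csv(path, index=False)


def read_genotype_table(path: PathLike, panel: LocusPanel) -> GenotypeSet:
    """Read a wide genotype CSV against a panel.

    Blank allele pairs are missing genotypes; an allele label outside the
    panel's allele list raises :class:`ValidationError` naming the locus
    and sample.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise SchemaError("genotype table missing mandatory column 'sample_id'")
    sample_ids = df["sample_id"].tolist()
    n = len(sample_ids)
    alleles = np.full((n, panel.n_loci, 2), -1, dtype=np.int16)
    for l, loc in enumerate(panel.loci):
        c1, c2 = f"{loc.locus_id}.1", f"{loc.locus_id}.2"
        if c1 not in df.columns or c2 not in df.columns:
            raise SchemaError(f"genotype table missing columns for locus {loc.locus_id!r}")
        lookup = {a: i for i, a in enumerate(loc.alleles)}
        for i, (a1, a2) in enumerate(zip(df[c1], df[c2])):
            a1, a2 = a1.strip(), a2.strip()
            if a1 == "" and a2 == "":
                continue
            if a1 == "" or a2 == "":
                raise ValidationError(
                    f"half-called genotype at locus {loc.locus_id}, sample {sample_ids[i]}"
                )
            try:
                alleles[i, l, 0] = lookup[a1]
                alleles[i, l, 1] = lookup[a2]
            except KeyError as e:
                raise ValidationError(
                    f"allele {e.args[0]!r} not in panel at locus {loc.locus_id}, "
                    f"sample {sample_ids[i]}"
                ) from None
    return GenotypeSet(sample_ids, alleles, panel)


# ----------------------------------------------------------------- config


def load_config(path: Optional[PathLike] = None, **overrides) -> Config:
    """Load a YAML config; absent keys take the package defaults
    (posterior_threshold 0.90, genotyping error 0.0054)."""
    data: dict = {}
    if path is not None:
        raw = Path(path).read_text()
        loaded = yaml.safe_load(raw)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config file must contain a mapping")
        data.update(loaded)
    data.update(overrides)
    known = {f for f in Config.__dataclass_fields__ if f != "extras"}
    extras = {k: v for k, v in data.items() if k not in known}
    kwargs = {k: v for k, v in data.items() if k in known}
    try:
        return Config(extras=extras, **kwargs)
    except (TypeError, ValueError) as e:
        raise ConfigError(str(e)) from e


def save_config(cfg: Config, path: PathLike) -> None:
    d = cfg.to_dict()
    extras = d.pop("extras", {})
    d.update(extras)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
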