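"""Compound datasets and structure handling.

The single source of truth for compound identifiers, experimental logBCF
values, logP values from multiple sources, and externally produced logBCF
predictions.  Structures are parsed with RDKit; salts are neutralised by
keeping the largest organic fragment.  All BCF work is in log10 units
(BCF itself is L/kg; its log10 is treated as dimensionless).
"""

from __future__ import annotations

import io
import logging
import math
import re
from contextlib import redirect_stderr
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from rdkit import Chem, rdBase

logger = logging.getLogger(__name__)

SPLIT_LABELS = ("training", "first_validation", "second_validation", "unlabelled")


class StructureParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a structure."""

    def __init__(self, smiles: str, message: str, position: int | None = None):
        self.smiles = smiles
        self.position = position
        where = f" near position {position}" if position is not None else ""
        super().__init__(f"cannot parse SMILES {smiles!r}{where}: {message}")


class DataError(ValueError):
    """A record or dataset violates a data contract."""


class ConfigError(ValueError):
    """A configuration (column map, generator config, ...) is invalid."""


@dataclass(frozen=True)
class Structure:
    """Immutable handle on a parsed molecule.

    Wraps the RDKit mol so downstream fragment matching never re-parses;
    ``canonical_smiles`` is the RDKit canonical form recorded at parse time.
    """

    mol: Chem.Mol
    canonical_smiles: str
    salt_stripped: bool = False

    @property
    def num_heavy_atoms(self) -> int:
        return self.mol.GetNumHeavyAtoms()

    @property
    def num_aromatic_atoms(self) -> int:
        return sum(1 for a in self.mol.GetAtoms() if a.GetIsAromatic())


_POSITION_RE = re.compile(r"position\s+(\d+)")


def parse_structure(smiles: str, strip_salts: bool = True) -> Structure:
    """Parse a SMILES string into an immutable :class:`Structure`.

    Multi-fragment inputs (salts) are reduced to the largest organic
    fragment when ``strip_salts`` is true; the action is logged.  Invalid
    syntax raises :class:`StructureParseError` naming the offending token
    position when RDKit's parser reports one.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise StructureParseError(str(smiles), "empty SMILES")
    smiles = smiles.strip()
    rdBase.LogToPythonStderr()
    buf = io.StringIO()
    with redirect_stderr(buf):
        mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        diag = buf.getvalue()
        m = _POSITION_RE.search(diag)
        pos = int(m.group(1)) if m else None
        reason = diag.strip().splitlines()[0] if diag.strip() else "syntax error"
        reason = re.sub(r"^\[[^\]]*\]\s*", "", reason)  # drop RDKit log timestamp
        raise StructureParseError(smiles, reason, position=pos)

    stripped = False
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1 and strip_salts:
        mol = _largest_organic_fragment(frags)
        stripped = True
        logger.info("stripped counter-ions from %s, kept %s", smiles, Chem.MolToSmiles(mol))
    return Structure(mol=mol, canonical_smiles=Chem.MolToSmiles(mol), salt_stripped=stripped)


def _largest_organic_fragment(frags: Sequence[Chem.Mol]) -> Chem.Mol:
    """Prefer carbon-containing fragments, then most heavy atoms."""

    def key(m: Chem.Mol):
        has_c = any(a.GetAtomicNum() == 6 for a in m.GetAtoms())
        return (has_c, m.GetNumHeavyAtoms())

    return max(frags, key=key)


@dataclass
class CompoundRecord:
    """One compound: structure, experimental values, logP sources.

    ``exp_logbcf`` holds every experimental log10 BCF value seen for this
    compound (duplicate dataset rows are merged, never averaged silently);
    ``logp`` keeps calculated/experimental logP values side by side keyed
    by source name (acd, kowwin, mdl, mlogp, experimental).
    """

    id: str
    smiles: str
    cas: str | None = None
    exp_logbcf: list[float] = field(default_factory=list)
    logp: dict[str, float] = field(default_factory=dict)
    predicted_logbcf: float | None = None
    descriptors: dict[str, float] | None = None
    structure: Structure | None = None

    def __post_init__(self):
        if not self.id:
            raise DataError("record id must be non-empty")
        for v in self.exp_logbcf:
            if not math.isfinite(v):
                raise DataError(f"record {self.id}: non-finite exp_logbcf value {v!r}")


def mean_exp_logbcf(record: CompoundRecord) -> float:
    """Arithmetic mean of the experimental log10 BCF values.

    Compounds frequently carry several measured BCF values; downstream
    statistics use their average.
    """
    if not record.exp_logbcf:
        raise DataError(f"record {record.id}: no experimental logBCF values")
    return sum(record.exp_logbcf) / len(record.exp_logbcf)


@dataclass
class Dataset:
    """Ordered collection of :class:`CompoundRecord` with unique ids."""

    records: list[CompoundRecord] = field(default_factory=list)
    split_label: str = "unlabelled"

    def __post_init__(self):
        if self.split_label not in SPLIT_LABELS:
            raise ConfigError(
                f"split_label {self.split_label!r} not one of {SPLIT_LABELS}"
            )
        seen: set[str] = set()
        for r in self.records:
            if r.id in seen:
                raise DataError(f"duplicate record id {r.id!r}")
            seen.add(r.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> CompoundRecord:
        return self.records[i]

    def get(self, record_id: str) -> CompoundRecord:
        for r in self.records:
            if r.id == record_id:
                return r
        raise KeyError(record_id)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]


@dataclass
class ReadReport:
    """Bookkeeping from a CSV read: accepted + rejected = input rows."""

    n_rows: int = 0
    n_accepted: int = 0
    rejected: list[tuple[str, str]] = field(default_factory=list)  # (id-or-row, reason)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


DEFAULT_COLUMN_MAP = {
    "id": "id",
    "smiles": "smiles",
    "cas": "cas",
    "bcf": "logbcf",
    "predicted": "predicted_logbcf",
    "bcf_units": "log",  # "log" or "linear"
    "logp_prefix": "logp_",
}


def read_dataset_csv(
    path,
    column_map: Mapping[str, str] | None = None,
    split_label: str = "unlabelled",
    parse_structures: bool = True,
) -> tuple[Dataset, ReadReport]:
    """Read a compound dataset from CSV.

    ``column_map`` names at least the ``id`` and ``smiles`` columns; the
    optional ``bcf`` column carries experimental BCF (log10 units by
    default; set ``bcf_units`` to ``"linear"`` for raw L/kg values, which
    are log10-transformed on read).  Rows sharing an id are merged: their
    experimental values accumulate in ``exp_logbcf``.  Rows whose SMILES
    does not parse are skipped and reported, never fatal.

    logP source columns are discovered by prefix (default ``logp_``):
    a column ``logp_mlogp`` becomes ``record.logp["mlogp"]``.  Descriptor
    columns use the prefix ``desc_``.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path)
    for required in (cmap["id"], cmap["smiles"]):
        if required not in df.columns:
            raise ConfigError(f"mandatory column {required!r} missing from {path}")

    linear_units = cmap.get("bcf_units", "log") == "linear"
    logp_prefix = cmap.get("logp_prefix", "logp_")
    report = ReadReport(n_rows=len(df))
    merged: dict[str, CompoundRecord] = {}

    for _, row in df.iterrows():
        rid = str(row[cmap["id"]])
        smi = row[cmap["smiles"]]
        structure = None
        if parse_structures:
            try:
                structure = parse_structure(str(smi))
            except StructureParseError as exc:
                report.rejected.append((rid, str(exc)))
                logger.warning("rejected row %s: %s", rid, exc)
                continue

        values: list[float] = []
        bcf_col = cmap.get("bcf")
        if bcf_col and bcf_col in df.columns and pd.notna(row[bcf_col]):
            v = float(row[bcf_col])
            if linear_units:
                if v <= 0:
                    report.rejected.append((rid, f"non-positive linear BCF {v}"))
                    continue
                v = math.log10(v)
            values.append(v)

        if rid in merged:
            merged[rid].exp_logbcf.extend(values)
            report.n_accepted += 1
            continue

        logp = {
            c[len(logp_prefix):]: float(row[c])
            for c in df.columns
            if c.startswith(logp_prefix) and pd.notna(row[c])
        }
        descriptors = {
            c[len("desc_"):]: float(row[c])
            for c in df.columns
            if c.startswith("desc_") and pd.notna(row[c])
        } or None
        pred_col = cmap.get("predicted")
        predicted = (
            float(row[pred_col])
            if pred_col and pred_col in df.columns and pd.notna(row[pred_col])
            else None
        )
        cas_col = cmap.get("cas")
        cas = (
            str(row[cas_col])
            if cas_col and cas_col in df.columns and pd.notna(row[cas_col])
            else None
        )
        merged[rid] = CompoundRecord(
            id=rid,
            smiles=str(smi),
            cas=cas,
            exp_logbcf=values,
            logp=logp,
            predicted_logbcf=predicted,
            descriptors=descriptors,
            structure=structure,
        )
        report.n_accepted += 1

    return Dataset(records=list(merged.values()), split_label=split_label), report


def read_smiles_file(path, parse_structures: bool = True) -> tuple[Dataset, ReadReport]:
    """Read a SMILES file: one record per line, ``SMILES<TAB>ID``."""
    records: list[CompoundRecord] = []
    report = ReadReport()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            report.n_rows += 1
            parts = line.split("\t")
            if len(parts) < 2:
                parts = line.split()
            if len(parts) < 2:
                report.rejected.append((f"line {lineno}", "expected SMILES<TAB>ID"))
                continue
            smi, rid = parts[0], parts[1]
            structure = None
            if parse_structures:
                try:
                    structure = parse_structure(smi)
                except StructureParseError as exc:
                    report.rejected.append((rid, str(exc)))
                    continue
            records.append(CompoundRecord(id=rid, smiles=smi, structure=structure))
            report.n_accepted += 1
    return Dataset(records=records), report


def write_predictions_csv(dataset: Dataset, results: Sequence, path) -> None:
    """Write predictions alongside compound identity to CSV.

    ``results`` is one :class:`bcfkit.classify.PredictionResult` (or any
    object with the same attributes) per record, in dataset order.  The
    output round-trips through :func:`read_dataset_csv`.
    """
    if len(results) != len(dataset):
        raise DataError(
            f"{len(results)} results for {len(dataset)} records; need one per record"
        )
    rows = []
    for rec, res in zip(dataset, results):
        rows.append(
            {
                "id": rec.id,
                "smiles": rec.smiles,
                "raw_logbcf": getattr(res, "raw_logbcf", None),
                "predicted_logbcf": getattr(res, "adjusted_logbcf", None),
                "bcf_class": str(getattr(res, "bcf_class", "")),
                "domain_verdict": getattr(res, "domain_verdict", ""),
                "warnings": ";".join(getattr(res, "warnings", []) or []),
            }
        )
    try:
        pd.DataFrame(
            rows,
            columns=[
                "id",
                "smiles",
                "raw_logbcf",
                "predicted_logbcf",
                "bcf_class",
                "domain_verdict",
                "warnings",
            ],
        ).to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"cannot write predictions to {path}: {exc}") from exc


def dataset_to_frame(dataset: Dataset) -> pd.DataFrame:
    """Flatten a dataset to a DataFrame (one row per record, values averaged)."""
    rows = []
    for r in dataset:
        row: dict = {"id": r.id, "smiles": r.smiles, "cas": r.cas}
        if r.exp_logbcf:
            row["logbcf"] = mean_exp_logbcf(r)
            row["n_exp_values"] = len(r.exp_logbcf)
        if r.predicted_logbcf is not None:
            row["predicted_logbcf"] = r.predicted_logbcf
        for src, v in r.logp.items():
            row[f"logp_{src}"] = v
        for name, v in (r.descriptors or {}).items():
            row[f"desc_{name}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
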