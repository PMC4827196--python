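"""Long-format qPCR data containers, I/O and validation.

A qPCR relative-quantification experiment is represented as a flat table of
quantification-cycle (Cq) observations.  Each row is one well (or one
replicate-averaged well) and carries the gene it measures, whether that gene
plays the *target* or *reference* role, the sample group (``case``,
``control`` or ``standard`` for the dilution series), a sample identifier,
the number of 2-fold dilutions applied, and the observed Cq.

The dilution coding follows the standard-curve convention in which
``dilution_steps = x`` means the template concentration was divided by
``2**x`` relative to the undiluted material, so the slope of Cq on
``dilution_steps`` is the inverse log2 amplification efficiency.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "CqRecord",
    "QpcrDataset",
    "QpcrFormatError",
    "QpcrValidationError",
    "read_cq_table",
    "write_cq_table",
    "validate_dataset",
    "average_technical_replicates",
    "dilution_steps_from_fold",
]

GENE_ROLES = ("target", "reference")
SAMPLE_GROUPS = ("case", "control", "standard")

_ROLE_SYNONYMS = {
    "target": "target", "tgt": "target",
    "reference": "reference", "ref": "reference",
}
_GROUP_SYNONYMS = {
    "case": "case",
    "control": "control", "ctrl": "control",
    "standard": "standard", "std": "standard",
}

CANONICAL_COLUMNS = (
    "gene_id", "gene_role", "sample_group", "sample_id", "dilution_steps", "cq",
)


class QpcrFormatError(ValueError):
    """Raised when an input table cannot be interpreted at all."""


class QpcrValidationError(ValueError):
    """Raised when a parsed table violates a dataset invariant."""


@dataclass(frozen=True)
class CqRecord:
    """One Cq observation (a well, or a replicate-averaged well)."""

    gene_id: str
    gene_role: str      # "target" | "reference"
    sample_group: str   # "case" | "control" | "standard"
    sample_id: str
    dilution_steps: float  # number of 2-fold dilutions; 0 = undiluted
    cq: float
    replicate_id: str | None = None

    def __post_init__(self):
        if self.gene_role not in GENE_ROLES:
            raise QpcrValidationError(f"unknown gene_role {self.gene_role!r}")
        if self.sample_group not in SAMPLE_GROUPS:
            raise QpcrValidationError(f"unknown sample_group {self.sample_group!r}")
        if not math.isfinite(self.cq):
            raise QpcrValidationError("cq must be finite")
        if self.dilution_steps < 0 or not math.isfinite(self.dilution_steps):
            raise QpcrValidationError("dilution_steps must be finite and >= 0")


@dataclass(frozen=True)
class QpcrDataset:
    """An immutable collection of :class:`CqRecord` plus analysis pairing.

    ``pairing`` maps each target ``gene_id`` to the reference ``gene_id`` it
    is normalised against.  Record order never affects downstream results;
    records are stored sorted on their identifying key.
    """

    records: tuple[CqRecord, ...]
    name: str = ""
    pairing: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        key = lambda r: (r.gene_id, r.gene_role, r.sample_group, r.sample_id,
                         r.dilution_steps, r.replicate_id or "")
        object.__setattr__(self, "records", tuple(sorted(self.records, key=key)))

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [r.gene_id for r in self.records],
                "gene_role": [r.gene_role for r in self.records],
                "sample_group": [r.sample_group for r in self.records],
                "sample_id": [r.sample_id for r in self.records],
                "dilution_steps": [r.dilution_steps for r in self.records],
                "replicate_id": [r.replicate_id for r in self.records],
                "cq": [r.cq for r in self.records],
            }
        )

    def genes(self, role: str | None = None) -> tuple[str, ...]:
        out = []
        for r in self.records:
            if role is None or r.gene_role == role:
                if r.gene_id not in out:
                    out.append(r.gene_id)
        return tuple(sorted(out))

    def subset_pair(self, target: str, reference: str) -> "QpcrDataset":
        """Restrict to one target/reference gene pair for a single analysis."""
        recs = [r for r in self.records
                if (r.gene_id == target and r.gene_role == "target")
                or (r.gene_id == reference and r.gene_role == "reference")]
        if not any(r.gene_role == "target" for r in recs):
            raise QpcrValidationError(f"no target records for gene {target!r}")
        if not any(r.gene_role == "reference" for r in recs):
            raise QpcrValidationError(f"no reference records for gene {reference!r}")
        return QpcrDataset(tuple(recs), name=f"{self.name}:{target} vs {reference}",
                           pairing={target: reference})

    def pairs(self) -> tuple[tuple[str, str], ...]:
        """Target/reference pairs to analyse.

        Uses ``pairing`` when provided; otherwise, with exactly one target
        and one reference gene present, that single pair.
        """
        if self.pairing:
            return tuple(sorted(self.pairing.items()))
        tg, rg = self.genes("target"), self.genes("reference")
        if len(tg) == 1 and len(rg) == 1:
            return ((tg[0], rg[0]),)
        raise QpcrValidationError(
            "ambiguous gene pairing; supply an explicit pairing map")


def dilution_steps_from_fold(k: float, fold: float) -> float:
    """Convert ``k`` serial dilutions with per-step factor ``fold`` to the
    2-fold coding used here: x = log2(fold**k)."""
    if fold <= 0:
        raise ValueError("fold factor must be positive")
    return k * math.log2(fold)


def _normalize(value: str, synonyms: Mapping[str, str], what: str, line: int) -> str:
    v = str(value).strip().lower()
    if v not in synonyms:
        raise QpcrValidationError(f"line {line}: unknown {what} {value!r}")
    return synonyms[v]


def read_cq_table(
    source,
    dialect: Mapping[str, str] | None = None,
    sep: str | None = None,
    name: str = "",
    pairing: Mapping[str, str] | None = None,
    allow_case_dilutions: bool = False,
) -> QpcrDataset:
    """Read a delimited Cq table into a validated :class:`QpcrDataset`.

    Parameters
    ----------
    source
        Path or text stream of a delimited file with a header.  Comma and
        tab separators are auto-detected unless ``sep`` is given.
    dialect
        Optional map from canonical column names (``gene_id``, ``gene_role``,
        ``sample_group``, ``sample_id``, ``dilution_steps``, ``cq``,
        optionally ``replicate_id``) to the names used in the file.
    allow_case_dilutions
        Case/control wells are normally required to be undiluted (x = 0);
        designs that dilute the biological samples themselves (group-specific
        efficiency estimation) set this to ``True``.
    """
    dialect = dict(dialect or {})
    if sep is None:
        # sniff the header line
        if hasattr(source, "read"):
            text = source.read()
            source = io.StringIO(text)
            header = text.splitlines()[0] if text else ""
        else:
            with open(source) as fh:
                header = fh.readline()
        sep = "\t" if header.count("\t") > header.count(",") else ","
    df = pd.read_csv(source, sep=sep, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]

    colmap = {canon: dialect.get(canon, canon) for canon in CANONICAL_COLUMNS}
    for canon, actual in colmap.items():
        if actual not in df.columns:
            raise QpcrFormatError(f"missing mandatory column {canon!r}"
                                  + (f" (mapped to {actual!r})" if actual != canon else ""))
    rep_col = dialect.get("replicate_id", "replicate_id")
    has_rep = rep_col in df.columns

    records = []
    for pos, row in enumerate(df.itertuples(index=False)):
        line = pos + 2  # header is line 1
        d = dict(zip(df.columns, row))
        try:
            x = float(d[colmap["dilution_steps"]])
            cq = float(d[colmap["cq"]])
        except (TypeError, ValueError) as exc:
            raise QpcrValidationError(f"line {line}: unparseable numeric field ({exc})")
        if not math.isfinite(cq):
            raise QpcrValidationError(f"line {line}: missing or non-finite cq")
        if x < 0:
            raise QpcrValidationError(f"line {line}: negative dilution_steps")
        group = _normalize(d[colmap["sample_group"]], _GROUP_SYNONYMS, "sample_group", line)
        role = _normalize(d[colmap["gene_role"]], _ROLE_SYNONYMS, "gene_role", line)
        if group in ("case", "control") and x != 0 and not allow_case_dilutions:
            raise QpcrValidationError(
                f"line {line}: {group} record with dilution_steps={x:g} violates "
                "the x=0 invariant for case/control wells")
        rep = d.get(rep_col) if has_rep else None
        if rep is not None and (pd.isna(rep) or str(rep).strip() == ""):
            rep = None
        records.append(CqRecord(
            gene_id=str(d[colmap["gene_id"]]).strip(),
            gene_role=role,
            sample_group=group,
            sample_id=str(d[colmap["sample_id"]]).strip(),
            dilution_steps=x,
            cq=cq,
            replicate_id=None if rep is None else str(rep).strip(),
        ))
    _check_unique(records)
    return QpcrDataset(tuple(records), name=name, pairing=dict(pairing or {}))


def _check_unique(records: Iterable[CqRecord]) -> None:
    seen = set()
    for r in records:
        key = (r.gene_id, r.sample_group, r.sample_id, r.dilution_steps, r.replicate_id)
        if key in seen:
            raise QpcrValidationError(f"duplicate record key {key}")
        seen.add(key)


def write_cq_table(ds: QpcrDataset, path_or_stream, sep: str = ",") -> None:
    """Write a dataset back to delimited text (round-trips with
    :func:`read_cq_table`)."""
    df = ds.to_frame()
    df.to_csv(path_or_stream, sep=sep, index=False)


def average_technical_replicates(ds: QpcrDataset) -> QpcrDataset:
    """Collapse technical replicates to their arithmetic-mean Cq.

    One record remains per (gene_id, gene_role, sample_group, sample_id,
    dilution_steps); records with no replicate duplication pass through
    unchanged (with replicate_id cleared).  Idempotent.
    """
    groups: dict[tuple, list[float]] = {}
    for r in ds.records:
        key = (r.gene_id, r.gene_role, r.sample_group, r.sample_id, r.dilution_steps)
        groups.setdefault(key, []).append(r.cq)
    records = tuple(
        CqRecord(gene_id=k[0], gene_role=k[1], sample_group=k[2], sample_id=k[3],
                 dilution_steps=k[4], cq=sum(v) / len(v))
        for k, v in groups.items()
    )
    return QpcrDataset(records, name=ds.name, pairing=dict(ds.pairing))


def validate_dataset(ds: QpcrDataset, spec) -> list[str]:
    """Check that ``ds`` supports fitting under ``spec``; returns a list of
    human-readable issues (empty iff the dataset is analyzable)."""
    issues: list[str] = []
    try:
        _check_unique(ds.records)
    except QpcrValidationError as exc:
        issues.append(str(exc))

    df = ds.to_frame()
    if df.empty:
        return ["dataset contains no records"]

    # case/control sample counts per role
    cc = df[df.sample_group.isin(["case", "control"])]
    for role in GENE_ROLES:
        for group in ("case", "control"):
            n = cc[(cc.gene_role == role) & (cc.sample_group == group)]["sample_id"].nunique()
            if n < 2:
                issues.append(f"fewer than 2 {group} samples for {role} gene (found {n})")

    structure = getattr(spec, "efficiency_structure", "estimated_shared")
    if structure == "estimated_shared":
        std = df[df.sample_group == "standard"]
        if std.empty:
            issues.append("no dilution data: estimated efficiencies require "
                          "standard-curve records")
        else:
            for role in GENE_ROLES:
                ndil = std[std.gene_role == role]["dilution_steps"].nunique()
                if 0 < ndil < 3:
                    issues.append(f"slope inestimable: standard curve for {role} "
                                  f"gene has only {ndil} distinct dilution steps")
                elif ndil == 0:
                    issues.append(f"no dilution data for {role} gene")
        if not cc[cc.sample_group.isin(["case", "control"])].dilution_steps.eq(0).all():
            issues.append("case/control records must have dilution_steps = 0 "
                          "under standard-curve efficiency estimation")
    elif structure == "estimated_by_group":
        for role in GENE_ROLES:
            for group in ("case", "control"):
                sub = df[(df.gene_role == role) & (df.sample_group == group)]
                if sub["dilution_steps"].nunique() < 3:
                    issues.append(f"slope inestimable: {role}/{group} has fewer than "
                                  "3 distinct dilution steps for group-specific efficiency")
    elif structure == "fixed_known":
        known = getattr(spec, "known_gamma", None) or {}
        if not known or any(g <= 0 for g in known.values()):
            issues.append("fixed_known efficiencies require strictly positive gamma values")

    if getattr(spec, "replicate_random_effect", False):
        if all(r.replicate_id is None for r in ds.records):
            issues.append("replicate random effect requested but no replicate_id present")
    return issues
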