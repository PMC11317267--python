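"""Readers and writers for the external formats the pipelines touch.

In-memory carriers:

* :class:`ExpressionMatrix` — non-negative gene × sample abundances.
* :class:`SignatureSet` — named gene lists parsed from GMT.
* :class:`RegulonSet` — TF → (targets, modes, confidence grade) mappings.
* :class:`LipidStudy` — paired baseline / week-6 lipid concentrations with
  a binary response label per patient.

All downstream modules consume only these types.  Identifiers are matched
case-sensitively after whitespace strip; missing values are rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from ._errors import ParseError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

RESPONSE_LABELS = ("R", "NR")
CONFIDENCE_GRADES = ("A", "B", "C", "D", "E")

#: float format giving bit-exact text round-trips for doubles
ROUNDTRIP_FMT = "%.17g"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Gene × sample abundance table (counts, TPM or normalized expression).

    The measurement unit is recorded as free-text metadata and not enforced.
    """

    values: pd.DataFrame  # genes as index, samples as columns
    unit: str = "unspecified"

    def __post_init__(self) -> None:
        v = self.values
        if not isinstance(v, pd.DataFrame):
            v = pd.DataFrame(v)
            self.values = v
        _check_unique(list(v.index), "gene")
        _check_unique(list(v.columns), "sample")
        self.values = v = v.astype(float)
        arr = v.to_numpy()
        if np.isnan(arr).any():
            g, s = np.argwhere(np.isnan(arr))[0]
            raise ValidationError(
                f"missing value at gene {v.index[g]!r}, sample {v.columns[s]!r}"
            )
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative value at gene {v.index[g]!r}, sample {v.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class SignatureSet:
    """Named, ordered gene lists (e.g. literature differentiation signatures)."""

    signatures: dict[str, list[str]]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.signatures.items():
            if not genes:
                raise ValidationError(f"signature {name!r} is empty")

    def __len__(self) -> int:
        return len(self.signatures)

    def __iter__(self) -> Iterator[str]:
        return iter(self.signatures)

    def __getitem__(self, name: str) -> list[str]:
        return self.signatures[name]

    def items(self):
        return self.signatures.items()


@dataclass
class Regulon:
    """One transcription factor's targets with regulation modes (+1/-1)."""

    tf: str
    targets: list[str]
    modes: list[int]
    confidence: str

    def __post_init__(self) -> None:
        if len(self.targets) != len(self.modes) or not self.targets:
            raise ValidationError(
                f"regulon {self.tf!r}: need equally many targets and modes (>=1)"
            )
        if any(m not in (1, -1) for m in self.modes):
            raise ValidationError(f"regulon {self.tf!r}: modes must be +1/-1")
        if self.confidence not in CONFIDENCE_GRADES:
            raise ValidationError(
                f"regulon {self.tf!r}: invalid confidence grade {self.confidence!r}"
            )


@dataclass
class RegulonSet:
    """TF → regulon mapping, typically confidence-filtered on read."""

    regulons: dict[str, Regulon]

    def __len__(self) -> int:
        return len(self.regulons)

    def __iter__(self) -> Iterator[str]:
        return iter(self.regulons)

    def __getitem__(self, tf: str) -> Regulon:
        return self.regulons[tf]

    def items(self):
        return self.regulons.items()


@dataclass
class LipidStudy:
    """Paired pre/post-treatment plasma lipid panel with response labels.

    ``baseline`` and ``week6`` are patient × lipid tables of strictly
    positive concentrations sharing identical indexing, so the per-patient
    log2 fold change is defined for every species.
    """

    baseline: pd.DataFrame  # patients × lipids
    week6: pd.DataFrame
    response: pd.Series  # per patient, in {R, NR}
    cohort: pd.Series  # per patient, free text

    def __post_init__(self) -> None:
        b, w = self.baseline, self.week6
        if not (b.index.equals(w.index) and b.columns.equals(w.columns)):
            raise ValidationError("baseline and week6 must share patient and lipid indexing")
        _check_unique(list(b.index), "patient")
        _check_unique(list(b.columns), "lipid")
        for name, tab in (("baseline", b), ("week6", w)):
            arr = tab.to_numpy(dtype=float)
            bad = ~(arr > 0)
            if bad.any():
                p, l = np.argwhere(bad)[0]
                raise ValidationError(
                    f"non-positive or missing {name} concentration for patient "
                    f"{tab.index[p]!r}, lipid {tab.columns[l]!r}"
                )
        for series, what in ((self.response, "response"), (self.cohort, "cohort")):
            if not series.index.equals(b.index):
                raise ValidationError(f"{what} labels must cover exactly the patients")
        bad = ~self.response.isin(RESPONSE_LABELS)
        if bad.any():
            pid = self.response.index[bad][0]
            raise ValidationError(
                f"unknown response token {self.response[pid]!r} for patient {pid!r}; "
                f"expected one of {RESPONSE_LABELS}"
            )

    @property
    def patient_ids(self) -> list[str]:
        return list(self.baseline.index)

    @property
    def lipid_ids(self) -> list[str]:
        return list(self.baseline.columns)


# ---------------------------------------------------------------------------
# expression matrix I/O
# ---------------------------------------------------------------------------


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("tsv", "csv", "mtx"):
        return suffix
    raise ParseError(f"cannot infer format from {path.name!r}; pass format=")


def read_expression(path: str | Path, format: str | None = None, unit: str = "unspecified") -> ExpressionMatrix:
    """Read a gene × sample expression table.

    Supported formats: ``tsv``/``csv`` (header row of sample ids, first
    column gene ids) and ``mtx`` (MatrixMarket with sidecar ``.rows`` /
    ``.cols`` name files).  Row/column order is preserved from the file.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    fmt = format or _infer_format(path)
    if fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
        df.index = df.index.astype(str).str.strip()
        df.columns = df.columns.astype(str).str.strip()
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                gene = df.index[bad][0]
                raise ParseError(
                    f"{path}: malformed numeric cell at gene {gene!r}, sample {col!r}"
                )
            df[col] = coerced
    elif fmt == "mtx":
        rows_file = path.with_suffix(".rows")
        cols_file = path.with_suffix(".cols")
        for side in (rows_file, cols_file):
            if not side.exists():
                raise ParseError(f"missing companion name file: {side}")
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:  # scipy raises bare ValueError on bad mtx
            raise ParseError(f"{path}: {exc}") from exc
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = [l.strip() for l in rows_file.read_text().splitlines() if l.strip()]
        samples = [l.strip() for l in cols_file.read_text().splitlines() if l.strip()]
        if mat.shape != (len(genes), len(samples)):
            raise ParseError(
                f"{path}: matrix shape {mat.shape} does not match "
                f"{len(genes)} row names x {len(samples)} column names"
            )
        df = pd.DataFrame(np.asarray(mat, dtype=float), index=genes, columns=samples)
    else:
        raise ParseError(f"unsupported expression format {fmt!r}")
    return ExpressionMatrix(values=df, unit=unit)


def write_expression(expr: ExpressionMatrix, path: str | Path, format: str | None = None) -> None:
    """Write an expression matrix; TSV/CSV uses 17-significant-digit floats."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        expr.values.to_csv(path, sep=sep, float_format=ROUNDTRIP_FMT)
    elif fmt == "mtx":
        scipy.io.mmwrite(path, expr.values.to_numpy(), precision=17)
        path.with_suffix(".rows").write_text("\n".join(expr.gene_ids) + "\n")
        path.with_suffix(".cols").write_text("\n".join(expr.sample_ids) + "\n")
    else:
        raise ParseError(f"unsupported expression format {fmt!r}")


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> SignatureSet:
    """Parse a GMT gene-set file: one signature per line,
    ``name<TAB>description<TAB>gene1<TAB>gene2...``.

    Duplicate genes within a signature are deduplicated preserving first
    occurrence; empty gene fields are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    signatures: dict[str, list[str]] = {}
    provenance: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
        name = fields[0].strip()
        if name in signatures:
            raise ValidationError(f"{path}:{lineno}: duplicate signature name {name!r}")
        genes: list[str] = []
        seen: set[str] = set()
        for g in fields[2:]:
            g = g.strip()
            if g and g not in seen:
                genes.append(g)
                seen.add(g)
        if not genes:
            raise ParseError(f"{path}:{lineno}: signature {name!r} has no genes")
        signatures[name] = genes
        provenance[name] = fields[1].strip()
    return SignatureSet(signatures=signatures, provenance=provenance)


def write_gmt(sigs: SignatureSet, path: str | Path) -> None:
    lines = []
    for name, genes in sigs.items():
        desc = sigs.provenance.get(name, "")
        lines.append("\t".join([name, desc, *genes]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# regulons
# ---------------------------------------------------------------------------

_MODE_TOKENS = {
    "+1": 1, "1": 1, "up": 1, "activation": 1,
    "-1": -1, "−1": -1, "down": -1, "repression": -1,
}


def read_regulons(
    path: str | Path,
    exclude_confidence: frozenset[str] | set[str] | None = frozenset({"E"}),
) -> RegulonSet:
    """Read a TF-target interaction table (columns tf, target, mode, confidence).

    Regulons whose confidence grade falls in ``exclude_confidence`` are
    dropped (default: the lowest-confidence E grade, keeping only curated
    and well-supported interactions).  Pass ``None`` or an empty set to
    keep everything.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"tf", "target", "mode", "confidence"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing regulon columns {sorted(missing)}")
    exclude = frozenset(exclude_confidence or ())
    regulons: dict[str, Regulon] = {}
    for tf, grp in df.groupby("tf", sort=False):
        grades = set(grp["confidence"].str.strip())
        if len(grades) != 1:
            raise ValidationError(f"{path}: regulon {tf!r} has mixed confidence grades")
        grade = grades.pop()
        if grade not in CONFIDENCE_GRADES:
            raise ValidationError(f"{path}: regulon {tf!r} has invalid grade {grade!r}")
        modes = []
        for tok in grp["mode"].str.strip():
            if tok not in _MODE_TOKENS:
                raise ParseError(f"{path}: unknown mode token {tok!r} in regulon {tf!r}")
            modes.append(_MODE_TOKENS[tok])
        if grade in exclude:
            logger.warning("regulon %s dropped (confidence %s excluded)", tf, grade)
            continue
        regulons[str(tf)] = Regulon(
            tf=str(tf),
            targets=[t.strip() for t in grp["target"]],
            modes=modes,
            confidence=grade,
        )
    if not regulons:
        logger.warning("%s: no regulons left after confidence filtering", path)
    return RegulonSet(regulons=regulons)


# ---------------------------------------------------------------------------
# lipid study
# ---------------------------------------------------------------------------

_BASE_SUF = "__baseline"
_WEEK_SUF = "__week6"


def read_lipid_study(
    path: str | Path,
    patient_col: str = "patient_id",
    response_col: str = "response",
    cohort_col: str = "cohort",
) -> LipidStudy:
    """Read a paired lipidomics CSV: one row per patient, a pair of columns
    ``<lipid>__baseline`` / ``<lipid>__week6`` per species, plus response
    (R/NR) and cohort labels.  Lipid panel order follows the file."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    for col in (patient_col, response_col, cohort_col):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    df[patient_col] = df[patient_col].astype(str).str.strip()
    df = df.set_index(patient_col)
    lipid_cols = [c for c in df.columns if c not in (response_col, cohort_col)]
    lipids: list[str] = []
    for c in lipid_cols:
        if c.endswith(_BASE_SUF):
            lipids.append(c[: -len(_BASE_SUF)])
        elif not c.endswith(_WEEK_SUF):
            raise SchemaError(
                f"{path}: column {c!r} is neither a label column nor a "
                f"'{_BASE_SUF}'/'{_WEEK_SUF}' pair member"
            )
    for l in lipids:
        if l + _WEEK_SUF not in df.columns:
            raise SchemaError(f"{path}: lipid {l!r} lacks its {_WEEK_SUF} partner column")
    extra_week = [
        c[: -len(_WEEK_SUF)]
        for c in lipid_cols
        if c.endswith(_WEEK_SUF) and c[: -len(_WEEK_SUF)] not in lipids
    ]
    if extra_week:
        raise SchemaError(
            f"{path}: lipid {extra_week[0]!r} lacks its {_BASE_SUF} partner column"
        )
    baseline = df[[l + _BASE_SUF for l in lipids]].astype(float)
    baseline.columns = lipids
    week6 = df[[l + _WEEK_SUF for l in lipids]].astype(float)
    week6.columns = lipids
    response = df[response_col].astype(str).str.strip()
    cohort = df[cohort_col].astype(str).str.strip()
    return LipidStudy(baseline=baseline, week6=week6, response=response, cohort=cohort)


def write_lipid_study(study: LipidStudy, path: str | Path) -> None:
    """Write a LipidStudy as the paired-column CSV read_lipid_study expects."""
    cols: list[pd.Series] = [
        study.response.rename("response"),
        study.cohort.rename("cohort"),
    ]
    for l in study.lipid_ids:
        cols.append(study.baseline[l].rename(l + _BASE_SUF))
        cols.append(study.week6[l].rename(l + _WEEK_SUF))
    out = pd.concat(cols, axis=1)
    out.index.name = "patient_id"
    out.to_csv(path, float_format=ROUNDTRIP_FMT)
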