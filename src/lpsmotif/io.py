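"""File formats and core containers for the LPS-tolerance motif pipeline.

Four external formats are handled here:

* expression matrices — tab-delimited text, one probe per row, a
  ``probe_id`` and ``gene_symbol`` column followed by replicate intensity
  columns named ``<condition>_<replicate>`` (conditions ``N``, ``NL``,
  ``TL`` and optionally ``T`` for the four-condition layout);
* promoter sequences — FASTA, one record per gene, headers optionally
  annotated ``window=-1000..+300 strand=+``; repeat-masked bases are ``N``;
* PWM libraries — TRANSFAC-style flat files (``AC``/``NA``/``P0`` blocks),
  plus a minimal per-motif TSV for de-novo output;
* curated TF -> target-gene lists — tab-delimited
  ``accession<TAB>tf_name<TAB>comma-separated targets``.

All expression computation downstream is probe-level; "gene"-level results
collapse probes by symbol, keeping the probe with the highest overall mean
intensity (see :meth:`ExpressionMatrix.collapse_by_symbol`).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Conditions understood by the pipeline, in canonical order.
#: N = untreated, NL = naive + 4 h LPS, T = 24 h LPS (tolerant),
#: TL = 24 h LPS then 4 h re-stimulation.
CONDITIONS = ("N", "NL", "T", "TL")

DNA_ALPHABET = "ACGTN"
_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


class FormatError(ValueError):
    """Raised when an input file violates its expected format."""


def normalize_symbol(symbol: str) -> str:
    """Canonical form of a gene symbol for comparison: trimmed, uppercased."""
    return symbol.strip().upper()


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionRecord:
    """One probe's intensities across conditions.

    ``values`` maps a condition name to a float array of replicate
    intensities (all non-negative, arbitrary scanner units). An empty
    ``gene_symbol`` marks an unannotated probe.
    """

    probe_id: str
    gene_symbol: str
    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for cond, vals in self.values.items():
            arr = np.asarray(vals, dtype=float)
            if arr.size < 1:
                raise FormatError(
                    f"probe {self.probe_id!r}: condition {cond!r} has no replicates"
                )
            if np.any(arr < 0) or not np.all(np.isfinite(arr)):
                raise FormatError(
                    f"probe {self.probe_id!r}: negative or non-finite intensity in {cond!r}"
                )
            clean[cond] = arr
        self.values = clean

    @property
    def annotated(self) -> bool:
        return bool(self.gene_symbol.strip())

    def mean(self, condition: str) -> float:
        if condition not in self.values:
            raise KeyError(f"probe {self.probe_id!r} has no condition {condition!r}")
        return float(self.values[condition].mean())

    def overall_mean(self) -> float:
        return float(np.concatenate(list(self.values.values())).mean())


@dataclass
class ExpressionMatrix:
    """An ordered collection of :class:`ExpressionRecord` sharing one design."""

    records: list[ExpressionRecord]
    condition_design: dict[str, int]

    def __post_init__(self) -> None:
        if not self.condition_design:
            raise FormatError("condition design is empty")
        seen: set[str] = set()
        for rec in self.records:
            if rec.probe_id in seen:
                raise FormatError(f"duplicate probe_id {rec.probe_id!r}")
            seen.add(rec.probe_id)
            if set(rec.values) != set(self.condition_design):
                raise FormatError(
                    f"probe {rec.probe_id!r} does not match the condition design"
                )
            for cond, n in self.condition_design.items():
                if rec.values[cond].size != n:
                    raise FormatError(
                        f"probe {rec.probe_id!r}: expected {n} replicates for {cond!r}"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def conditions(self) -> list[str]:
        return [c for c in CONDITIONS if c in self.condition_design]

    @property
    def probe_ids(self) -> list[str]:
        return [r.probe_id for r in self.records]

    @property
    def n_probes(self) -> int:
        return len(self.records)

    @property
    def n_annotated(self) -> int:
        return sum(1 for r in self.records if r.annotated)

    def values(self, condition: str) -> np.ndarray:
        """Replicate intensities for one condition, shape (n_probes, n_reps)."""
        return np.vstack([r.values[condition] for r in self.records])

    def means(self, condition: str) -> np.ndarray:
        return self.values(condition).mean(axis=1)

    def get(self, probe_id: str) -> ExpressionRecord:
        for r in self.records:
            if r.probe_id == probe_id:
                return r
        raise KeyError(probe_id)

    def collapse_by_symbol(self) -> "ExpressionMatrix":
        """One record per gene symbol: the probe with the highest overall mean.

        Unannotated probes are dropped. Record order follows the first
        appearance of each symbol.
        """
        best: dict[str, ExpressionRecord] = {}
        order: list[str] = []
        for rec in self.records:
            if not rec.annotated:
                continue
            key = normalize_symbol(rec.gene_symbol)
            if key not in best:
                best[key] = rec
                order.append(key)
            elif rec.overall_mean() > best[key].overall_mean():
                best[key] = rec
        return ExpressionMatrix([best[k] for k in order], dict(self.condition_design))


def _parse_sample_column(name: str) -> tuple[str, int]:
    m = re.fullmatch(r"([A-Za-z]+)_(\d+)", name)
    if not m:
        raise FormatError(f"sample column {name!r} is not of the form <condition>_<rep>")
    cond = m.group(1).upper()
    if cond not in CONDITIONS:
        raise FormatError(f"sample column {name!r}: unknown condition {cond!r}")
    return cond, int(m.group(2))


def read_expression_matrix(
    path: str | Path,
    condition_design: dict[str, int] | None = None,
) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix.

    The header must start with ``probe_id`` and ``gene_symbol`` followed by
    sample columns ``<condition>_<replicate>``.  When ``condition_design`` is
    given, the file's columns must cover exactly that design; otherwise the
    design is inferred from the header.  Rows with non-numeric or negative
    intensities raise :class:`FormatError` naming the offending line.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise FormatError(f"{path}: empty file")
        cols = header.split("\t")
        if cols[:2] != ["probe_id", "gene_symbol"]:
            raise FormatError(
                f"{path}: header must start with 'probe_id\\tgene_symbol' (got {cols[:2]})"
            )
        sample_cols = [(_parse_sample_column(c), i) for i, c in enumerate(cols[2:], start=2)]
        design: dict[str, int] = {}
        for (cond, _rep), _ in sample_cols:
            design[cond] = design.get(cond, 0) + 1
        if condition_design is not None and design != dict(condition_design):
            missing = set(condition_design) - set(design)
            if missing:
                raise FormatError(f"{path}: missing condition column(s) {sorted(missing)}")
            raise FormatError(
                f"{path}: column design {design} does not match requested {condition_design}"
            )

        records: list[ExpressionRecord] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(cols):
                raise FormatError(
                    f"{path} line {lineno}: expected {len(cols)} fields, got {len(fields)}"
                )
            values: dict[str, list[float]] = {c: [] for c in design}
            for (cond, _rep), idx in sample_cols:
                raw = fields[idx]
                try:
                    val = float(raw)
                except ValueError:
                    raise FormatError(
                        f"{path} line {lineno}: non-numeric intensity {raw!r} in column {cols[idx]!r}"
                    ) from None
                if not np.isfinite(val) or val < 0:
                    raise FormatError(
                        f"{path} line {lineno}: invalid (negative/non-finite) intensity {raw!r}"
                    )
                values[cond].append(val)
            records.append(ExpressionRecord(fields[0], fields[1], {c: np.array(v) for c, v in values.items()}))
    matrix = ExpressionMatrix(records, design)
    logger.info(
        "read %d probes (%d annotated) from %s", matrix.n_probes, matrix.n_annotated, path
    )
    return matrix


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    conds = matrix.conditions
    header = ["probe_id", "gene_symbol"]
    for c in conds:
        header += [f"{c}_{i + 1}" for i in range(matrix.condition_design[c])]
    with path.open("w") as fh:
        fh.write("\t".join(header) + "\n")
        for rec in matrix.records:
            row = [rec.probe_id, rec.gene_symbol]
            for c in conds:
                row += [format(v, "g") for v in rec.values[c]]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Promoter sequences
# ---------------------------------------------------------------------------

@dataclass
class PromoterSequence:
    """A promoter window around a TSS, default -1000..+300, repeats as N."""

    gene_id: str
    sequence: str
    window: tuple[int, int] = (-1000, 300)
    strand: str = "+"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set(DNA_ALPHABET)
        if bad:
            raise FormatError(
                f"promoter {self.gene_id!r}: characters outside ACGTN: {sorted(bad)}"
            )
        if len(self.sequence) == 0:
            raise FormatError(f"promoter {self.gene_id!r}: zero-length sequence")
        if self.strand not in "+-":
            raise FormatError(f"promoter {self.gene_id!r}: bad strand {self.strand!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def expected_length(self) -> int:
        return self.window[1] - self.window[0] + 1


_WINDOW_RE = re.compile(r"window=(-?\d+)\.\.([+-]?\d+)")
_STRAND_RE = re.compile(r"strand=([+-])")


def read_fasta_promoters(
    path: str | Path,
    expected_window: tuple[int, int] = (-1000, 300),
) -> list[PromoterSequence]:
    """Read promoters from FASTA, parsing window/strand annotations.

    Sequences are uppercased; characters outside ACGTN are rejected.
    Records shorter than the declared window are accepted with a logged
    warning (genes near contig ends); motif scans simply use what is there.
    Duplicate gene ids and empty records are errors.
    """
    path = Path(path)
    promoters: list[PromoterSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate gene_id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description
        m = _WINDOW_RE.search(desc)
        window = (int(m.group(1)), int(m.group(2))) if m else tuple(expected_window)
        ms = _STRAND_RE.search(desc)
        strand = ms.group(1) if ms else "+"
        prom = PromoterSequence(rec.id, str(rec.seq), window, strand)
        if len(prom) != prom.expected_length:
            logger.warning(
                "promoter %s: length %d differs from window length %d (truncated promoter?)",
                rec.id, len(prom), prom.expected_length,
            )
        promoters.append(prom)
    if not promoters:
        raise FormatError(f"{path}: no FASTA records")
    return promoters


def write_fasta_promoters(promoters: Sequence[PromoterSequence], path: str | Path) -> None:
    records = [
        SeqRecord(
            Seq(p.sequence),
            id=p.gene_id,
            description=f"window={p.window[0]}..+{p.window[1]} strand={p.strand}"
            if p.window[1] >= 0
            else f"window={p.window[0]}..{p.window[1]} strand={p.strand}",
        )
        for p in promoters
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Position weight matrices
# ---------------------------------------------------------------------------

@dataclass
class PWM:
    """A column-stochastic position weight matrix (rows = positions, A C G T)."""

    accession: str
    tf_name: str
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise FormatError(f"PWM {self.accession!r}: matrix must be width x 4")
        if self.probs.shape[0] < 4:
            raise FormatError(f"PWM {self.accession!r}: width must be >= 4")
        if np.any(self.probs < 0):
            raise FormatError(f"PWM {self.accession!r}: negative probabilities")
        sums = self.probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise FormatError(f"PWM {self.accession!r}: columns do not sum to 1")

    @property
    def width(self) -> int:
        return int(self.probs.shape[0])

    @classmethod
    def from_counts(
        cls, accession: str, tf_name: str, counts: np.ndarray, pseudocount: float = 0.5
    ) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        if np.any(counts.sum(axis=1) <= 0):
            raise FormatError(f"PWM {accession!r}: a position has zero total count")
        probs = counts + pseudocount
        probs /= probs.sum(axis=1, keepdims=True)
        return cls(accession, tf_name, probs)

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.probs.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(self.accession, self.tf_name, self.probs[::-1, ::-1].copy())

    def information_content(self, background: np.ndarray | None = None) -> float:
        """Total information content in bits relative to the background."""
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        p = np.clip(self.probs, 1e-12, None)
        return float(np.sum(p * np.log2(p / bg)))

    def log_odds(self, background: np.ndarray | None = None, floor: float = 1e-4) -> np.ndarray:
        """Per-position log-odds scores vs a 0-order background (natural log)."""
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        p = np.clip(self.probs, floor, None)
        return np.log(p / bg)


def read_pwm_library(path: str | Path, pseudocount: float = 0.5) -> list[PWM]:
    """Parse a TRANSFAC-style flat file into PWMs.

    Accepts both count and frequency rows; a pseudocount (default 0.5 per
    cell) is added before normalization so zero counts never produce zero
    probabilities.  Duplicate accessions and all-zero positions are errors.
    """
    path = Path(path)
    text = path.read_text()
    return parse_pwm_library(text, pseudocount=pseudocount, source=str(path))


def parse_pwm_library(text: str, pseudocount: float = 0.5, source: str = "<string>") -> list[PWM]:
    pwms: list[PWM] = []
    seen: set[str] = set()
    accession: str | None = None
    tf_name = ""
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal accession, tf_name, rows
        if accession is None:
            return
        if not rows:
            raise FormatError(f"{source}: matrix {accession!r} has no position rows")
        counts = np.array(rows, dtype=float)
        if np.any(counts.sum(axis=1) <= 0):
            raise FormatError(f"{source}: matrix {accession!r} has a zero-total position")
        if accession in seen:
            raise FormatError(f"{source}: duplicate accession {accession!r}")
        seen.add(accession)
        pwms.append(PWM.from_counts(accession, tf_name, counts, pseudocount=pseudocount))
        accession, tf_name, rows = None, "", []

    for raw in text.splitlines():
        line = raw.rstrip()
        if not line or line.startswith(("XX", "CC", "BF")):
            continue
        if line.startswith("//"):
            flush()
            continue
        tag, _, rest = line.partition(" ")
        rest = rest.strip()
        if tag == "AC":
            flush()
            accession = rest
        elif tag == "NA":
            tf_name = rest
        elif tag in ("ID", "DE"):
            if not tf_name:
                tf_name = rest
        elif tag == "P0" or tag == "PO":
            continue
        elif re.fullmatch(r"\d+", tag):
            parts = rest.split()
            if len(parts) < 4:
                raise FormatError(f"{source}: malformed matrix row {line!r}")
            try:
                rows.append([float(x) for x in parts[:4]])
            except ValueError:
                raise FormatError(f"{source}: non-numeric matrix row {line!r}") from None
    flush()
    if not pwms:
        raise FormatError(f"{source}: no matrices found")
    return pwms


def write_pwm_library(pwms: Sequence[PWM], path: str | Path) -> None:
    """Write PWMs as a TRANSFAC-style flat file (probability rows)."""
    with Path(path).open("w") as fh:
        for pwm in pwms:
            fh.write(f"AC  {pwm.accession}\nXX\nNA  {pwm.tf_name}\nXX\n")
            fh.write("P0      A      C      G      T\n")
            for i, row in enumerate(pwm.probs, start=1):
                cells = "  ".join(format(v, ".6f") for v in row)
                fh.write(f"{i:02d}  {cells}  {_BASES[int(row.argmax())]}\n")
            fh.write("XX\n//\n")


def write_pwm_tsv(pwm: PWM, path: str | Path) -> None:
    """Minimal per-motif TSV (columns A, C, G, T) for de-novo output."""
    with Path(path).open("w") as fh:
        fh.write(f"# accession={pwm.accession} tf={pwm.tf_name}\n")
        fh.write("A\tC\tG\tT\n")
        for row in pwm.probs:
            fh.write("\t".join(format(v, ".6f") for v in row) + "\n")


def read_pwm_tsv(path: str | Path) -> PWM:
    path = Path(path)
    accession, tf_name = path.stem, ""
    rows: list[list[float]] = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            m = re.search(r"accession=(\S+)", line)
            if m:
                accession = m.group(1)
            m = re.search(r"tf=(\S+)", line)
            if m:
                tf_name = m.group(1)
            continue
        if line.strip() in ("", "A\tC\tG\tT"):
            continue
        rows.append([float(x) for x in line.split("\t")])
    probs = np.array(rows)
    probs /= probs.sum(axis=1, keepdims=True)
    return PWM(accession, tf_name, probs)


# ---------------------------------------------------------------------------
# Curated TF -> target lists
# ---------------------------------------------------------------------------

@dataclass
class TargetAssociation:
    """A profile TF (library accession) with its curated target genes."""

    matrix_accession: str
    tf_name: str
    targets: list[str]
    evidence: str = "curated"

    def __post_init__(self) -> None:
        deduped: list[str] = []
        seen: set[str] = set()
        for t in self.targets:
            t = t.strip()
            if not t:
                continue
            key = normalize_symbol(t)
            if key not in seen:
                seen.add(key)
                deduped.append(t)
        if not deduped:
            raise FormatError(
                f"association {self.matrix_accession!r}/{self.tf_name!r}: empty target list"
            )
        self.targets = deduped

    @property
    def target_keys(self) -> set[str]:
        return {normalize_symbol(t) for t in self.targets}


def read_target_lists(path: str | Path) -> list[TargetAssociation]:
    """Read ``accession<TAB>tf_name<TAB>comma-separated targets`` rows.

    Target symbols are deduplicated case-insensitively (first spelling kept).
    A header line starting with ``accession`` is skipped.
    """
    path = Path(path)
    associations: list[TargetAssociation] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if lineno == 1 and fields[0].lower() in ("accession", "matrix_accession"):
            continue
        if len(fields) < 3:
            raise FormatError(f"{path} line {lineno}: expected 3 tab-separated fields")
        acc, tf, targets = fields[0].strip(), fields[1].strip(), fields[2]
        if not targets.strip():
            raise FormatError(f"{path} line {lineno}: empty target field")
        associations.append(TargetAssociation(acc, tf, targets.split(",")))
    if not associations:
        raise FormatError(f"{path}: no associations found")
    return associations


def write_target_lists(associations: Sequence[TargetAssociation], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("accession\ttf_name\ttargets\n")
        for a in associations:
            fh.write(f"{a.matrix_accession}\t{a.tf_name}\t{','.join(a.targets)}\n")


def load_curated_targets() -> list[TargetAssociation]:
    """The bundled curated profile-TF target-gene fixture (12 associations)."""
    from importlib.resources import files

    path = files("lpsmotif.data") / "profile_tf_targets.tsv"
    return read_target_lists(Path(str(path)))
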