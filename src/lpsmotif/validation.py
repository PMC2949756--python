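"""Literature-target validation of predicted profile TFs.

Curated TF -> target-gene lists are intersected with the relaxed two-fold
pro-inflammatory signature; overlapping targets are checked for the
pro-inflammatory expression pattern, given Figure-style relative expression
profiles, optionally re-checked in an independent four-condition dataset
(the tolerizability cross-check), and contrasted against seeded random gene
sets of the same size.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

from .io import ExpressionMatrix, TargetAssociation, normalize_symbol
from .classify import (
    RelativeExpressionProfile,
    TwofoldSignature,
    _twofold_pass,
    cross_dataset_pattern,
    random_gene_pattern_null,
    relative_profiles,
    twofold_signature,
)

logger = logging.getLogger(__name__)


@dataclass
class ValidationReport:
    signature_size: int
    overlap_genes: list[str]
    overlap_count: int
    pattern_pass_count: int
    unique_target_count: int
    cross_dataset_pass_count: int | None = None
    cross_dataset_flags: dict[str, bool] | None = None
    random_null_counts: list[int] | None = None
    profiles: list[RelativeExpressionProfile] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.pattern_pass_count <= self.overlap_count <= max(self.signature_size, 0)):
            raise ValueError("inconsistent validation counts")

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["profiles"] = [asdict(p) for p in self.profiles]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def overlap_targets(
    associations: list[TargetAssociation],
    signature,
) -> list[str]:
    """Deduplicated union of curated targets intersected with the signature.

    Comparison is case-insensitive; the returned spellings are the
    signature's.  ``signature`` may be a :class:`TwofoldSignature` or any
    iterable of gene symbols.
    """
    genes = signature.genes if isinstance(signature, TwofoldSignature) else list(signature)
    sig_by_key = {}
    for g in genes:
        sig_by_key.setdefault(normalize_symbol(g), g)
    target_keys: set[str] = set()
    for a in associations:
        target_keys |= a.target_keys
    hits = sorted(sig_by_key[k] for k in target_keys & set(sig_by_key))
    return hits


def unique_target_count(associations: list[TargetAssociation]) -> int:
    keys: set[str] = set()
    for a in associations:
        keys |= a.target_keys
    return len(keys)


def validate(
    matrix: ExpressionMatrix,
    associations: list[TargetAssociation],
    second_matrix: ExpressionMatrix | None = None,
    seed: int | None = None,
    fold: float = 2.0,
    n_random_sets: int = 10,
) -> ValidationReport:
    """Full literature-target validation against one expression matrix.

    Builds the two-fold signature, overlaps it with the curated targets,
    flags the pro-inflammatory pattern per overlapping gene (on a signature
    built from the same matrix this passes by construction — the
    interesting case is a different matrix or threshold), emits relative
    expression profiles, runs the four-condition cross-dataset check when
    ``second_matrix`` is given, and samples random same-size gene sets as a
    null when ``seed`` is given.
    """
    signature = twofold_signature(matrix, fold=fold)
    overlap = overlap_targets(associations, signature)

    collapsed = matrix.collapse_by_symbol()
    by_key = {normalize_symbol(r.gene_symbol): r for r in collapsed}
    pattern_pass = 0
    for gene in overlap:
        rec = by_key.get(normalize_symbol(gene))
        if rec is not None and _twofold_pass(rec, fold):
            pattern_pass += 1

    profiles = relative_profiles(matrix, overlap)

    cross_count = None
    cross_flags = None
    if second_matrix is not None:
        cross_flags, cross_count = cross_dataset_pattern(second_matrix, overlap)

    null_counts = None
    if seed is not None and overlap:
        null_counts = random_gene_pattern_null(
            matrix, set_size=len(overlap), n_sets=n_random_sets, seed=seed, fold=fold
        )

    report = ValidationReport(
        signature_size=len(signature),
        overlap_genes=overlap,
        overlap_count=len(overlap),
        pattern_pass_count=pattern_pass,
        unique_target_count=unique_target_count(associations),
        cross_dataset_pass_count=cross_count,
        cross_dataset_flags=cross_flags,
        random_null_counts=null_counts,
        profiles=profiles,
    )
    logger.info(
        "validation: signature=%d overlap=%d pattern_pass=%d cross=%s",
        report.signature_size, report.overlap_count, report.pattern_pass_count,
        report.cross_dataset_pass_count,
    )
    return report
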