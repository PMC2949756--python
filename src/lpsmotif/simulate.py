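"""Seeded synthetic data: expression matrices, promoters, PWM library, targets.

The generator emulates the statistical structure of a two-replicate
three-condition (optionally four-condition) macrophage LPS-tolerance
microarray together with its promoter sequences and a small TF matrix
library:

* baseline intensities are lognormal across genes; replicates carry
  multiplicative lognormal noise with a chosen coefficient of variation;
* a planted *pro-inflammatory* class is induced ``induction_fold`` from N
  to N+L and repressed from N+L to T+L — genes whose promoter carries a
  planted TF site get the full ``repression_fold``, carrier-free class
  members a weaker ``weak_repression_fold`` (motif occupancy is what drives
  the stronger silencing, so the expression response carries information
  about the motif);
* a planted *antibacterial* class is induced and then further escalated;
* promoters are 0-order background with repeat-mask N runs, and planted PWM
  sites are sampled column-wise from the PWM at random offsets and strands;
* the library holds the planted PWMs plus information-content-matched
  decoys, and the curated-target file lists a subset of each planted TF's
  carrier genes plus decoy entries.

A :class:`TruthManifest` records every planted fact for scoring recovery.
Everything is deterministic under the config seed, including emitted bytes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io import (
    PWM,
    ExpressionMatrix,
    ExpressionRecord,
    PromoterSequence,
    TargetAssociation,
    write_expression_matrix,
    write_fasta_promoters,
    write_pwm_library,
    write_target_lists,
)
from . import seqs as sq

logger = logging.getLogger(__name__)

CLASS_PRO = "pro"
CLASS_ANTI = "anti"
CLASS_NULL = "null"


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic bundle."""

    n_genes: int = 1000
    frac_pro: float = 0.10
    frac_anti: float = 0.02
    induction_fold: float = 20.0
    repression_fold: float = 2.5
    weak_repression_fold: float = 2.0
    anti_escalation_fold: float = 1.5
    replicate_cv: float = 0.05
    n_replicates: int = 2
    include_tolerant_condition: bool = False
    baseline_log_mean: float = 5.5   # natural-log intensity scale (~245 units)
    baseline_log_sd: float = 1.0
    promoter_length: int = 1300
    background_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    planted_width: int = 10
    n_planted: int = 1
    insertion_probability: float = 0.6
    sites_per_carrier: int = 1
    n_decoys: int = 8
    mask_run_rate: float = 0.02   # expected masked fraction of each promoter
    mask_run_length: int = 30
    n_curated_targets: int = 15
    n_decoy_target_entries: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.frac_pro + self.frac_anti <= 1:
            raise ValueError("class fractions must sum to at most 1")
        if min(self.induction_fold, self.repression_fold,
               self.weak_repression_fold, self.anti_escalation_fold) <= 1:
            raise ValueError("fold changes must exceed 1")
        if self.replicate_cv < 0:
            raise ValueError("replicate_cv must be >= 0")
        comp = np.asarray(self.background_composition, float)
        if abs(comp.sum() - 1.0) > 1e-9 or np.any(comp < 0):
            raise ValueError("background composition must be a probability vector")


@dataclass
class TruthManifest:
    """Ground truth planted into a bundle."""

    gene_class: dict[str, str] = field(default_factory=dict)
    carriers: dict[str, list[str]] = field(default_factory=dict)   # accession -> genes
    occurrences: list[dict] = field(default_factory=list)          # gene/accession/offset/strand
    planted_targets: dict[str, list[str]] = field(default_factory=dict)  # accession -> curated subset

    def genes_of_class(self, label: str) -> list[str]:
        return [g for g, c in self.gene_class.items() if c == label]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)


def _rng(config: SyntheticConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def _sharp_pwm(rng: np.random.Generator, width: int, accession: str, tf_name: str) -> PWM:
    """A well-determined random PWM: one dominant base per position.

    The 0.92 dominant probability gives ~1.47 bits per column (~14.7 bits
    for the default width of 10), in the range of curated TF matrices and
    comfortably above the ~11.3 bits needed to localize a single site in a
    1300-bp window — a planted motif below that bound is undetectable in
    principle, not just in practice.
    """
    probs = np.empty((width, 4))
    for k in range(width):
        dominant = int(rng.integers(4))
        p = np.full(4, 0.08 / 3)
        p[dominant] = 0.92
        probs[k] = p / p.sum()
    return PWM(accession, tf_name, probs)


def default_planted_pwms(config: SyntheticConfig) -> list[PWM]:
    rng = _rng(config, 10)
    return [
        _sharp_pwm(rng, config.planted_width, f"PLT{i + 1:03d}", f"PlantedTF{i + 1}")
        for i in range(config.n_planted)
    ]


def generate_expression(config: SyntheticConfig) -> tuple[ExpressionMatrix, TruthManifest]:
    """Expression matrix with planted phenotype classes.

    Carrier status (whether a pro gene's promoter will receive a planted
    site) is drawn here with ``insertion_probability`` and recorded in the
    manifest; :func:`generate_promoters` plants sites exactly where the
    manifest says.  Carriers get the full repression fold, non-carriers the
    weak one.
    """
    rng = _rng(config, 1)
    n = config.n_genes
    n_pro = int(round(config.frac_pro * n))
    n_anti = int(round(config.frac_anti * n))
    labels = np.array([CLASS_PRO] * n_pro + [CLASS_ANTI] * n_anti
                      + [CLASS_NULL] * (n - n_pro - n_anti))
    rng.shuffle(labels)

    genes = [f"GENE{i + 1:04d}" for i in range(n)]
    manifest = TruthManifest(gene_class=dict(zip(genes, labels)))

    planted = default_planted_pwms(config)
    pro_genes = [g for g, c in zip(genes, labels) if c == CLASS_PRO]
    for pwm in planted:
        flips = rng.random(len(pro_genes)) < config.insertion_probability
        manifest.carriers[pwm.accession] = [g for g, f in zip(pro_genes, flips) if f]

    carrier_set = set().union(*manifest.carriers.values()) if manifest.carriers else set()

    base = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n))
    conditions = ["N", "NL", "TL"] + (["T"] if config.include_tolerant_condition else [])
    sigma = float(np.sqrt(np.log1p(config.replicate_cv ** 2)))

    records: list[ExpressionRecord] = []
    for i, (gene, label) in enumerate(zip(genes, labels)):
        means = {"N": base[i], "NL": base[i], "TL": base[i], "T": base[i]}
        if label == CLASS_PRO:
            means["NL"] = base[i] * config.induction_fold
            rep = config.repression_fold if gene in carrier_set else config.weak_repression_fold
            means["TL"] = means["NL"] / rep
        elif label == CLASS_ANTI:
            means["NL"] = base[i] * config.induction_fold
            means["TL"] = means["NL"] * config.anti_escalation_fold
        values = {}
        for cond in conditions:
            if sigma > 0:
                noise = np.exp(rng.normal(-sigma ** 2 / 2, sigma, size=config.n_replicates))
            else:
                noise = np.ones(config.n_replicates)
            values[cond] = means[cond] * noise
        records.append(ExpressionRecord(f"P{i + 1:05d}_at", gene, values))

    matrix = ExpressionMatrix(records, {c: config.n_replicates for c in conditions})
    logger.info("synthetic expression: %d genes (%d pro, %d anti)", n, n_pro, n_anti)
    return matrix, manifest


def _sample_site(pwm: PWM, rng: np.random.Generator) -> str:
    letters = [sq.BASES[rng.choice(4, p=col / col.sum())] for col in pwm.probs]
    return "".join(letters)


def generate_promoters(
    config: SyntheticConfig, manifest: TruthManifest
) -> list[PromoterSequence]:
    """Background promoters with mask runs and manifest-designated plants."""
    rng = _rng(config, 2)
    comp = np.asarray(config.background_composition, float)
    planted = {p.accession: p for p in default_planted_pwms(config)}
    L = config.promoter_length
    window = (-1000, L - 1001)

    promoters: list[PromoterSequence] = []
    for gene in manifest.gene_class:
        chars = np.array(list(sq.BASES))[rng.choice(4, size=L, p=comp)]
        # repeat masking: N runs covering ~mask_run_rate of the promoter
        n_runs = rng.poisson(config.mask_run_rate * L / config.mask_run_length)
        for _ in range(n_runs):
            start = int(rng.integers(0, max(1, L - config.mask_run_length)))
            chars[start : start + config.mask_run_length] = "N"

        occupied: list[tuple[int, int]] = []
        for acc, pwm in planted.items():
            if gene not in manifest.carriers.get(acc, []):
                continue
            w = pwm.width
            if L < w:
                raise ValueError(f"promoter length {L} too short for planted width {w}")
            for _ in range(config.sites_per_carrier):
                site = _sample_site(pwm, rng)
                strand = "+" if rng.random() < 0.5 else "-"
                placed = False
                for _attempt in range(200):
                    off = int(rng.integers(0, L - w + 1))
                    span = (off, off + w)
                    if any(span[0] < e and s < span[1] for s, e in occupied):
                        continue
                    if np.any(chars[span[0] : span[1]] == "N"):
                        continue
                    ins = site if strand == "+" else sq.revcomp(site)
                    chars[span[0] : span[1]] = list(ins)
                    occupied.append(span)
                    manifest.occurrences.append(
                        {"gene": gene, "accession": acc, "offset": off, "strand": strand}
                    )
                    placed = True
                    break
                if not placed:
                    raise ValueError(
                        f"could not place a planted site in promoter of {gene} "
                        f"(length {L}, masked fraction too high?)"
                    )
        promoters.append(PromoterSequence(gene, "".join(chars), window))
    return promoters


def _decoy_pwm(planted: PWM, rng: np.random.Generator, accession: str, tf_name: str) -> PWM:
    """Decoy with the planted PWM's information content: per-column letter
    permutations in shuffled column order."""
    cols = planted.probs.copy()
    order = rng.permutation(cols.shape[0])
    out = np.empty_like(cols)
    for i, j in enumerate(order):
        perm = rng.permutation(4)
        out[i] = cols[j][perm]
    return PWM(accession, tf_name, out)


def generate_library_and_targets(
    config: SyntheticConfig, manifest: TruthManifest
) -> tuple[list[PWM], list[TargetAssociation]]:
    """Planted PWMs plus IC-matched decoys, and consistent curated targets.

    Curated targets of a planted TF are a subset of its carrier genes
    (biological curation never covers every target); decoy TFs get random
    null-class genes so their lists never show the planted pattern.
    """
    rng = _rng(config, 3)
    planted = default_planted_pwms(config)
    library: list[PWM] = list(planted)
    for i in range(config.n_decoys):
        template = planted[i % len(planted)]
        library.append(_decoy_pwm(template, rng, f"DCY{i + 1:03d}", f"DecoyTF{i + 1}"))

    associations: list[TargetAssociation] = []
    for pwm in planted:
        carriers = manifest.carriers.get(pwm.accession, [])
        if not carriers:
            continue
        k = min(config.n_curated_targets, len(carriers))
        idx = rng.choice(len(carriers), size=k, replace=False)
        targets = sorted(carriers[i] for i in idx)
        manifest.planted_targets[pwm.accession] = targets
        associations.append(TargetAssociation(pwm.accession, pwm.tf_name, targets))

    null_genes = manifest.genes_of_class(CLASS_NULL)
    decoys = [p for p in library if p.accession.startswith("DCY")]
    if null_genes:
        for i in range(min(config.n_decoy_target_entries, len(decoys))):
            k = min(config.n_curated_targets, len(null_genes))
            idx = rng.choice(len(null_genes), size=k, replace=False)
            associations.append(
                TargetAssociation(decoys[i].accession, decoys[i].tf_name,
                                  sorted(null_genes[j] for j in idx))
            )
    return library, associations


@dataclass
class SyntheticBundle:
    config: SyntheticConfig
    matrix: ExpressionMatrix
    promoters: list[PromoterSequence]
    library: list[PWM]
    targets: list[TargetAssociation]
    manifest: TruthManifest

    @property
    def planted_accessions(self) -> list[str]:
        return [p.accession for p in self.library if p.accession.startswith("PLT")]


def generate_bundle(config: SyntheticConfig | None = None, **overrides) -> SyntheticBundle:
    """Generate a complete, internally consistent synthetic bundle."""
    if config is None:
        config = SyntheticConfig(**overrides)
    elif overrides:
        raise ValueError("pass either a config or keyword overrides, not both")
    matrix, manifest = generate_expression(config)
    promoters = generate_promoters(config, manifest)
    library, targets = generate_library_and_targets(config, manifest)
    return SyntheticBundle(config, matrix, promoters, library, targets, manifest)


def write_bundle(bundle: SyntheticBundle, out_dir) -> dict[str, Path]:
    """Write all bundle files; byte-identical across runs at a fixed seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "expression.tsv",
        "promoters": out / "promoters.fasta",
        "library": out / "library.transfac",
        "targets": out / "targets.tsv",
        "manifest": out / "manifest.json",
    }
    write_expression_matrix(bundle.matrix, paths["matrix"])
    write_fasta_promoters(bundle.promoters, paths["promoters"])
    write_pwm_library(bundle.library, paths["library"])
    write_target_lists(bundle.targets, paths["targets"])
    bundle.manifest.to_json(paths["manifest"])
    return paths
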