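"""End-to-end characterization run: wires every stage together and writes
the TSV/Newick report bundle.

Outputs are a pure function of (inputs, config, seeds): every report header
embeds the package version and a hash of the resolved configuration, and no
timestamps are written, so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .composition import codon_profile, composition_summary, extract_region
from .genome import (
    CircularGenome,
    GeneClass,
    organization_report,
    pcg_union_length,
    read_annotation_table,
    read_fasta,
    write_organization_tsv,
)
from .phylo import bootstrap_support, root_with_outgroup, tn93_matrix
from .repeats import count_tandem_copies
from .variation import (
    DEFAULT_CYTB_SCHEME,
    AlignmentMatrix,
    HaplotypeScheme,
    classify_haplotype,
    polymorphic_sites,
    variable_fraction,
)

__all__ = ["ConfigError", "RunConfig", "run_characterization"]

logger = logging.getLogger(__name__)

SEQUENCE_STAGES = ("organize", "composition", "rscu", "repeats")
ALIGNMENT_STAGES = ("variation", "haplotype", "phylo")


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    genome_fasta: str
    annotation_tsv: str
    outdir: str
    alignment_fasta: str | None = None
    stages: tuple[str, ...] = SEQUENCE_STAGES
    outgroup: str | None = None
    replicates: int = 1000
    seed: int = 42
    reference_row: str | None = None
    repeat_motif: str = "CGTACACGTG"
    repeat_max_mismatch: int = 0
    haplotype_positions: tuple[int, ...] = DEFAULT_CYTB_SCHEME.positions
    haplotype_labels: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CYTB_SCHEME.labels)
    )
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a YAML config; keyword overrides (CLI flags) win."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        return cfg

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        self.haplotype_positions = tuple(self.haplotype_positions)
        bad = [s for s in self.stages if s not in SEQUENCE_STAGES + ALIGNMENT_STAGES]
        if bad:
            raise ConfigError(f"unknown stages: {bad}")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")

    def config_hash(self) -> str:
        # outdir and log level do not affect results, so they stay out of
        # the hash and identical analyses hash identically
        payload = dataclasses.asdict(self)
        payload.pop("outdir")
        payload.pop("log_level")
        blob = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def validate_paths(self) -> None:
        for p in (self.genome_fasta, self.annotation_tsv):
            if not Path(p).exists():
                raise ConfigError(f"input not found: {p}")
        needs_aln = [s for s in self.stages if s in ALIGNMENT_STAGES]
        if needs_aln:
            if self.alignment_fasta is None:
                raise ConfigError(
                    f"stages {needs_aln} need an alignment, none configured"
                )
            if not Path(self.alignment_fasta).exists():
                raise ConfigError(f"alignment not found: {self.alignment_fasta}")


def _header(cfg: RunConfig) -> str:
    return f"# mitochar {__version__}\tconfig_hash={cfg.config_hash()}\n"


def _fmt(value: float | None, digits: int) -> str:
    return "undefined" if value is None else f"{value:.{digits}f}"


def _write_composition_tsv(genome: CircularGenome, cfg: RunConfig, path: Path) -> None:
    rows = [("whole_genome", genome.seq)]
    pcgs = genome.features_of_class(GeneClass.PCG)
    if pcgs:
        rows.append(("PCGs_concatenated", "".join(extract_region(genome, f) for f in pcgs)))
    for f in genome.features:
        if f.gene_class in (GeneClass.RRNA, GeneClass.CONTROL):
            rows.append((f.name, extract_region(genome, f)))
    for f in pcgs:
        rows.append((f.name, extract_region(genome, f)))
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        fh.write("region\tlength\tT\tC\tA\tG\tat_percent\tat_skew\tgc_skew\n")
        for label, seq in rows:
            s = composition_summary(seq, label)
            fh.write(
                f"{label}\t{s.length}\t{s.percent['T']:.1f}\t{s.percent['C']:.1f}\t"
                f"{s.percent['A']:.1f}\t{s.percent['G']:.1f}\t{s.at_percent:.1f}\t"
                f"{_fmt(s.at_skew, 6)}\t{_fmt(s.gc_skew, 6)}\n"
            )
        fh.write(f"# pcg_union_bp\t{pcg_union_length(genome)}\n")


def _write_rscu_tsv(genome: CircularGenome, cfg: RunConfig, outdir: Path) -> list[Path]:
    profile = codon_profile(genome)
    rscu_path = outdir / "rscu.tsv"
    with open(rscu_path, "w") as fh:
        fh.write(_header(cfg))
        fh.write("codon\tamino_acid\tcount\trscu\n")
        from .composition import SYNONYMOUS_FAMILIES

        for aa, family in sorted(SYNONYMOUS_FAMILIES.items()):
            for codon in family:
                fh.write(
                    f"{codon}\t{aa}\t{profile.counts.get(codon, 0)}\t"
                    f"{profile.rscu[codon]:.3f}\n"
                )
    aa_path = outdir / "aa_distribution.tsv"
    with open(aa_path, "w") as fh:
        fh.write(_header(cfg))
        fh.write("amino_acid\tpercent\n")
        for aa, pct in profile.aa_percent.items():
            fh.write(f"{aa}\t{pct:.2f}\n")
    genes_path = outdir / "gene_codons.tsv"
    with open(genes_path, "w") as fh:
        fh.write(_header(cfg))
        fh.write("gene\tstart_codon\tstop_status\n")
        for gene in sorted(profile.gene_start):
            fh.write(
                f"{gene}\t{profile.gene_start[gene]}\t{profile.gene_stop_status[gene]}\n"
            )
    return [rscu_path, aa_path, genes_path]


def run_characterization(cfg: RunConfig) -> dict[str, Path]:
    """Run the configured stages; returns output paths keyed by stage name.

    Raises :class:`ConfigError` before any work when the configuration is
    inconsistent (e.g. an alignment stage without an alignment).
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    cfg.validate_paths()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    seq = read_fasta(cfg.genome_fasta)
    features = read_annotation_table(cfg.annotation_tsv, len(seq))
    genome = CircularGenome(seq=seq, features=features)
    logger.info(
        "loaded genome: %d bp, %d features (config %s)",
        genome.length,
        len(features),
        cfg.config_hash(),
    )

    if "organize" in cfg.stages:
        path = outdir / "organization.tsv"
        report = organization_report(genome)
        write_organization_tsv(report, path)
        outputs["organize"] = path
        logger.info(
            "organize: %d genes, %d overlaps (%d bp), %d spacers (%d bp)",
            report.gene_count,
            report.overlap_count,
            report.overlap_total_bp,
            report.spacer_count,
            report.spacer_total_bp,
        )

    if "composition" in cfg.stages:
        path = outdir / "composition.tsv"
        _write_composition_tsv(genome, cfg, path)
        outputs["composition"] = path

    if "rscu" in cfg.stages:
        outputs["rscu"] = _write_rscu_tsv(genome, cfg, outdir)[0]

    if "repeats" in cfg.stages:
        controls = genome.features_of_class(GeneClass.CONTROL)
        if not controls:
            raise ConfigError("repeats stage needs a control-class feature")
        region = extract_region(genome, controls[0])
        rep = count_tandem_copies(region, cfg.repeat_motif, cfg.repeat_max_mismatch)
        path = outdir / "repeats.tsv"
        with open(path, "w") as fh:
            fh.write(_header(cfg))
            fh.write("motif\tcopy_number\trun_start\tmax_mismatch\tregion_length\n")
            fh.write(
                f"{rep.motif}\t{rep.copy_number}\t{rep.run_start or ''}\t"
                f"{cfg.repeat_max_mismatch}\t{len(region)}\n"
            )
        outputs["repeats"] = path

    aln: AlignmentMatrix | None = None
    if any(s in cfg.stages for s in ALIGNMENT_STAGES):
        aln = AlignmentMatrix.from_fasta(cfg.alignment_fasta)

    if "variation" in cfg.stages:
        assert aln is not None
        sites = polymorphic_sites(aln)
        path = outdir / "variation.tsv"
        enc_rows = dict(zip(aln.names, aln.seqs))
        with open(path, "w") as fh:
            fh.write(_header(cfg))
            fh.write("column\t" + "\t".join(aln.names) + "\n")
            for col in sites:
                fh.write(
                    f"{col}\t" + "\t".join(enc_rows[n][col - 1] for n in aln.names) + "\n"
                )
            fh.write(f"# polymorphic_sites\t{len(sites)}\n")
            fh.write(f"# variable_fraction_percent\t{variable_fraction(aln):.2f}\n")
        outputs["variation"] = path

    if "haplotype" in cfg.stages:
        assert aln is not None
        scheme = HaplotypeScheme(
            positions=cfg.haplotype_positions, labels=dict(cfg.haplotype_labels)
        )
        path = outdir / "haplotypes.tsv"
        with open(path, "w") as fh:
            fh.write(_header(cfg))
            fh.write("sample\thaplotype\n")
            for name, row in zip(aln.names, aln.seqs):
                fh.write(f"{name}\t{classify_haplotype(row, scheme)}\n")
        outputs["haplotype"] = path

    if "phylo" in cfg.stages:
        assert aln is not None
        dist_path = outdir / "distances.tsv"
        tn93_matrix(aln).to_tsv(dist_path)
        result = bootstrap_support(aln, replicates=cfg.replicates, seed=cfg.seed)
        tree = result.tree
        if cfg.outgroup is not None:
            tree = root_with_outgroup(tree, cfg.outgroup)
        path = outdir / "tree.nwk"
        path.write_text(tree.newick() + "\n")
        outputs["phylo"] = path
        logger.info(
            "phylo: %d replicates (%d dropped), tree written to %s",
            result.replicates,
            result.dropped,
            path,
        )

    return outputs
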