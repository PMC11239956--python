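"""Readers, writers and the end-to-end pipeline driver.

Formats: VCF 4.x (biallelic SNP genotypes, GT field), aligned FASTA,
labels / occurrences / forcing CSV, and ESRI ASCII grids (re-exported
from :mod:`skyisland.paleoenm.grids`).  ``run_pipeline`` ties the stages
together from a single YAML config and writes a provenance manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from .genotypes import GenotypeMatrix
from .sequences import SequenceAlignment
from .paleoenm.grids import read_ascii_grid, write_ascii_grid  # noqa: F401

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_fasta",
    "write_fasta",
    "read_labels",
    "write_labels",
    "read_ascii_grid",
    "write_ascii_grid",
    "PipelineConfig",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# VCF
# ----------------------------------------------------------------------

def read_vcf(path, labels: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read biallelic SNP records into a dosage matrix.

    Genotypes become alt-allele counts (0/1/2); ``./.`` becomes missing.
    Multiallelic records are skipped with a logged count.  ``labels`` is a
    DataFrame with columns individual/population[/group]; without it all
    individuals land in one population.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError("VCF has no sample columns (missing GT data)")
    locus_ids: list[str] = []
    rows: list[np.ndarray] = []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gt = rec.gt_types.astype(float)
        dosage = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], np.nan)
        rows.append(dosage)
        locus_ids.append(f"{rec.CHROM}:{rec.POS}")
    if n_multi:
        logger.warning("skipped %d multiallelic records", n_multi)
    if not rows:
        raise ValueError("no biallelic records found")
    G = np.column_stack(rows) if rows else np.empty((len(samples), 0))

    if labels is not None:
        lab = labels.set_index("individual")
        missing = [s for s in samples if s not in lab.index]
        if missing:
            raise ValueError(f"labels CSV missing individuals: {missing}")
        population = [str(lab.loc[s, "population"]) for s in samples]
        group = (
            [str(lab.loc[s, "group"]) for s in samples]
            if "group" in lab.columns else None
        )
    else:
        population = ["pop1"] * len(samples)
        group = None
    return GenotypeMatrix(
        genotypes=G,
        individual_ids=samples,
        population=population,
        group=group,
        locus_ids=locus_ids,
    )


def write_vcf(path, g: GenotypeMatrix) -> None:
    """Write a dosage matrix as a minimal VCFv4.2 text file."""
    gt_strings = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.individual_ids) + "\n"
        )
        for j, lid in enumerate(g.locus_ids):
            calls = [
                "./." if np.isnan(x) else gt_strings[x] for x in g.genotypes[:, j]
            ]
            fh.write(
                f"1\t{j + 1}\t{lid}\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


# ----------------------------------------------------------------------
# FASTA and labels
# ----------------------------------------------------------------------

def read_fasta(path, labels: pd.DataFrame | None = None,
               species_delimiter: str | None = None) -> SequenceAlignment:
    """Read an aligned FASTA; optionally attach species labels.

    Labels come either from a CSV DataFrame (columns individual, species)
    or, with ``species_delimiter``, from the last delimiter-separated
    field of each FASTA id.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    ids = [r.id for r in records]
    seqs = [str(r.seq).upper() for r in records]
    species = None
    if labels is not None:
        lab = labels.set_index("individual")
        species = [str(lab.loc[i, "species"]) for i in ids]
    elif species_delimiter is not None:
        species = [i.split(species_delimiter)[-1] for i in ids]
    return SequenceAlignment(ids=ids, sequences=seqs, species=species)


def write_fasta(path, aln: SequenceAlignment) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="")
        for i, s in zip(aln.ids, aln.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_labels(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if "individual" not in frame.columns:
        raise ValueError("labels CSV needs an 'individual' column")
    return frame


def write_labels(path, g: GenotypeMatrix) -> None:
    g.labels_frame().to_csv(path, index=False)


# ----------------------------------------------------------------------
# Pipeline
# ----------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Settings for the simulate → popgen → cluster demonstration pipeline."""

    out_dir: str = "skyisland_out"
    seed: int = 0
    # genotype simulation
    n_groups: int = 2
    pops_per_group: int = 3
    inds_per_pop: int = 20
    n_loci: int = 500
    fct_target: float = 0.30
    fsc_target: float = 0.02
    missing_rate: float = 0.05
    # filters and tests
    min_call_fraction: float = 0.5
    min_populations: int = 6
    n_permutations: int = 999
    # clustering
    k_min: int = 1
    k_max: int = 6
    n_axes: int = 50

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate genotypes, run popgen statistics and clustering, write outputs.

    Every output is recorded in a provenance manifest (inputs, settings,
    seed, package version) written as ``manifest.json``.
    """
    from . import __version__, clustering, popgen, synthdata

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    spec = synthdata.SimGenotypeSpec(
        n_groups=config.n_groups,
        pops_per_group=config.pops_per_group,
        inds_per_pop=config.inds_per_pop,
        n_loci=config.n_loci,
        fct_target=config.fct_target,
        fsc_target=config.fsc_target,
        missing_rate=config.missing_rate,
        seed=config.seed,
    )
    g = synthdata.simulate_hierarchical_genotypes(spec)
    write_vcf(out / "genotypes.vcf", g)
    write_labels(out / "labels.csv", g)
    logger.info("simulated genotypes: %d x %d", g.n_individuals, g.n_loci)

    g_filt, report = popgen.completeness_filter(
        g, config.min_call_fraction, config.min_populations
    )
    report.to_csv(out / "locus_filter.csv", index=False)
    stats = popgen.locus_statistics(g_filt)
    stats.to_csv(out / "locus_stats.csv", index=False)

    amova = popgen.amova(
        g_filt, hierarchy="groups/pops",
        n_permutations=config.n_permutations, seed=config.seed,
    )
    amova.to_frame().to_csv(out / "amova.csv", index=False)

    fst = popgen.pairwise_phi_st(
        g_filt, n_permutations=config.n_permutations, seed=config.seed
    )
    fst.to_frame("fst").to_csv(out / "fst_raw.csv")
    fst.to_frame("fst_floored").to_csv(out / "fst_floored.csv")
    fst.to_frame("linearized").to_csv(out / "fst_linearized.csv")

    model = clustering.dapc_pipeline(
        g_filt, n_axes=config.n_axes, k_min=config.k_min,
        k_max=config.k_max, seed=config.seed,
    )
    pd.DataFrame(
        {"k": list(model.bic_by_k), "bic": list(model.bic_by_k.values())}
    ).to_csv(out / "bic.csv", index=False)
    pd.DataFrame(
        model.membership_probabilities,
        index=g_filt.individual_ids,
        columns=[f"cluster_{c}" for c in range(model.k)],
    ).to_csv(out / "membership.csv")
    pd.DataFrame(
        {"individual": g_filt.individual_ids, "cluster": model.cluster_assignments}
    ).to_csv(out / "clusters.csv", index=False)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "settings": dataclasses.asdict(config),
        "outputs": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
        "summary": {
            "n_individuals": g.n_individuals,
            "n_loci_simulated": g.n_loci,
            "n_loci_kept": g_filt.n_loci,
            "phi_ct": amova.phi_ct,
            "phi_st": amova.phi_st,
            "best_k": model.k,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
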