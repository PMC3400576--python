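"""End-to-end pipeline: simulate -> demux -> trim -> collapse -> map ->
annotate -> quantify -> report.

A run is fully described by a :class:`RunConfig` (loadable from YAML);
identical config and seed produce byte-identical outputs.  Machine
outputs go to files under the run's output directory; progress and
discard counts are logged to standard error.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .annotate import LocusIndex, annotate_collapsed
from .genome import GenomeBundle, generate_genome
from .mapper import GenomeIndex
from .preprocess import demultiplex, preprocess_library, read_fastq_sequences, write_collapsed_fasta
from .quantify import (
    LibrarySummary,
    class_counts,
    length_distribution,
    length_profiles,
    normalize_rpm,
    ratio_21u_to_mirna,
    subclass_ratio,
    tail_frequency,
    SIRNA_CLASSES,
)
from .simulate import (
    DEFAULT_ADAPTER,
    GENOTYPES,
    TreatmentSpec,
    genotype_preset,
    simulate_library,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration; raised before any stage executes."""


DEFAULT_LOCUS_PLAN = {"21U": 30, "miRNA": 8, "mRNA": 16, "rRNA": 1, "tRNA": 2}


@dataclass
class LibraryConfig:
    library_id: str
    genotype: str = "wild-type"
    barcode: str = "ACTA"
    oxidized: bool = False
    tap_treated: bool = False
    depth: int = 100_000


@dataclass
class Thresholds:
    min_raw: float = 250.0
    csr1_rpm: float = 500.0
    csr1_ratio: float = 0.9
    de_fold: float = 2.0
    de_alpha: float = 0.05


@dataclass
class RunConfig:
    """Every numeric setting of the pipeline in one place.

    With ``simulate`` true a genome and the listed libraries are
    generated; otherwise ``genome_fasta``/``genome_gff3`` and
    ``lane_fastqs`` must point at existing inputs.
    """

    out_dir: str
    seed: int = 7
    simulate: bool = True
    n_chrom: int = 1
    chrom_lengths: List[int] = field(default_factory=lambda: [50_000])
    locus_plan: Dict[str, int] = field(default_factory=lambda: dict(DEFAULT_LOCUS_PLAN))
    libraries: List[LibraryConfig] = field(default_factory=list)
    adapter: str = DEFAULT_ADAPTER
    read_length: int = 50
    min_overlap: int = 6
    min_len: int = 18
    seed_len: int = 18
    multimap: str = "fractional"
    unmethylated_ox_survival: float = 0.05
    triphosphate_clonability: float = 0.05
    thresholds: Thresholds = field(default_factory=Thresholds)
    genome_fasta: Optional[str] = None
    genome_gff3: Optional[str] = None
    lane_fastqs: List[str] = field(default_factory=list)

    def __post_init__(self):
        if isinstance(self.thresholds, dict):
            self.thresholds = Thresholds(**self.thresholds)
        self.libraries = [
            LibraryConfig(**lib) if isinstance(lib, dict) else lib
            for lib in self.libraries
        ]

    def validate(self) -> None:
        if not self.libraries:
            raise ConfigError("at least one library must be configured")
        for lib in self.libraries:
            if lib.genotype not in GENOTYPES:
                raise ConfigError(f"unknown genotype preset {lib.genotype!r}")
            if len(lib.barcode) != 4:
                raise ConfigError(f"{lib.library_id}: barcode must be 4 nt")
            if lib.depth < 1:
                raise ConfigError(f"{lib.library_id}: depth must be >= 1")
        ids = [l.library_id for l in self.libraries]
        if len(set(ids)) != len(ids):
            raise ConfigError("library_id values must be unique")
        if not self.simulate:
            if not (self.genome_fasta and self.genome_gff3):
                raise ConfigError(
                    "genome_fasta and genome_gff3 are required when simulate is off"
                )
            if not self.lane_fastqs:
                raise ConfigError("lane_fastqs are required when simulate is off")
        for t in ("min_raw", "csr1_rpm", "csr1_ratio", "de_fold", "de_alpha"):
            if getattr(self.thresholds, t) <= 0:
                raise ConfigError(f"threshold {t} must be positive")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Hash of the run-defining settings (paths excluded)."""
        d = self.to_dict()
        for key in ("out_dir", "genome_fasta", "genome_gff3", "lane_fastqs"):
            d.pop(key, None)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages: Dict[str, dict]

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _assign_lanes(libraries: Sequence[LibraryConfig]) -> List[List[LibraryConfig]]:
    """Group libraries into two-barcode lanes (distinct barcodes per lane)."""
    lanes: List[List[LibraryConfig]] = []
    for lib in libraries:
        for lane in lanes:
            if len(lane) < 2 and all(l.barcode != lib.barcode for l in lane):
                lane.append(lib)
                break
        else:
            lanes.append([lib])
    return lanes


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: Dict[str, dict] = {}

    # ---------------------------------------------------------------- genome
    if config.simulate:
        bundle = generate_genome(
            config.n_chrom, config.chrom_lengths, config.locus_plan,
            seed=config.seed, write_dir=out,
        )
    else:
        bundle = GenomeBundle.from_files(config.genome_fasta, config.genome_gff3)
    stages["genome"] = {
        "n_chrom": len(bundle.chromosomes),
        "n_loci": len(bundle.loci),
    }

    # -------------------------------------------------------------- simulate
    lanes = _assign_lanes(config.libraries)
    lane_files: List[Path] = []
    lane_barcodes: List[List[str]] = []
    sim_stats: Dict[str, dict] = {}
    if config.simulate:
        for lane_i, lane in enumerate(lanes):
            lane_path = out / f"lane_{lane_i + 1}.fastq"
            with open(lane_path, "w") as fh:
                for lib_i, lib in enumerate(lane):
                    params = genotype_preset(lib.genotype)
                    treatment = TreatmentSpec(
                        oxidized=lib.oxidized,
                        tap_treated=lib.tap_treated,
                        unmethylated_ox_survival=config.unmethylated_ox_survival,
                        triphosphate_clonability=config.triphosphate_clonability,
                    )
                    # fixed per-library sub-stream offsets off the master seed
                    lib_index = config.libraries.index(lib)
                    lib_seed = (config.seed + 1009 * (lib_index + 1)) % (2**31)
                    sim = simulate_library(
                        bundle, params, treatment, lib.depth,
                        barcode=lib.barcode, adapter=config.adapter,
                        read_length=config.read_length, seed=lib_seed,
                    )
                    for rid, seq in sim.reads:
                        fh.write(f"@{lib.library_id}_{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
                    sim.write_truth(out / f"truth_{lib.library_id}.tsv")
                    sim_stats[lib.library_id] = dict(sim.stats)
                    logger.info(
                        "simulated %s: %d/%d reads emitted",
                        lib.library_id, sim.stats["emitted"], lib.depth,
                    )
            lane_files.append(lane_path)
            lane_barcodes.append([l.barcode for l in lane])
    else:
        lane_files = [Path(p) for p in config.lane_fastqs]
        lane_barcodes = [[l.barcode for l in lane] for lane in lanes]
    stages["simulate"] = sim_stats

    # ----------------------------------------------------------------- demux
    by_library: Dict[str, List[str]] = {}
    demux_stats: Dict[str, dict] = {}
    for lane_i, (lane_path, lane) in enumerate(zip(lane_files, lanes)):
        seqs = read_fastq_sequences(lane_path)
        assigned, discarded = demultiplex(seqs, [l.barcode for l in lane])
        for lib in lane:
            by_library[lib.library_id] = assigned[lib.barcode]
        demux_stats[f"lane_{lane_i + 1}"] = {
            "input": len(seqs),
            "assigned": {l.library_id: len(assigned[l.barcode]) for l in lane},
            "discarded_barcode": discarded,
        }
        logger.info("lane %d: %d reads, %d barcode failures",
                    lane_i + 1, len(seqs), discarded)
    stages["demux"] = demux_stats

    # ----------------------------------------------- trim + collapse + map
    index = GenomeIndex(bundle.chromosomes, k=config.seed_len)
    loci = LocusIndex(bundle.loci)
    annotated: Dict[str, pd.DataFrame] = {}
    prep_stats: Dict[str, dict] = {}
    map_stats: Dict[str, dict] = {}
    for lib in config.libraries:
        collapsed, pstats = preprocess_library(
            by_library[lib.library_id], config.adapter,
            min_overlap=config.min_overlap, min_len=config.min_len,
        )
        prep_stats[lib.library_id] = pstats
        write_collapsed_fasta(out / f"collapsed_{lib.library_id}.fasta", collapsed)
        df, mstats = annotate_collapsed(
            collapsed, index, loci, multimap=config.multimap
        )
        annotated[lib.library_id] = df
        map_stats[lib.library_id] = mstats
        df.to_csv(out / f"annotated_{lib.library_id}.tsv", sep="\t", index=False)
        logger.info(
            "%s: %d unique inserts, mapped weight %.1f, unmapped %.1f, too short %.1f",
            lib.library_id, len(collapsed), mstats["mapped_weight"],
            mstats["unmapped_weight"], mstats["too_short_weight"],
        )
    stages["preprocess"] = prep_stats
    stages["map"] = map_stats

    # -------------------------------------------------------------- quantify
    quant = quantify_libraries(annotated, config.thresholds)
    write_report(quant, out)
    stages["quantify"] = {
        lib_id: {"classes": {k: round(v, 6) for k, v in summary.raw.items()}}
        for lib_id, summary in quant["summaries"].items()
    }

    manifest = RunManifest(
        config_hash=config.config_hash(), version=__version__, stages=stages
    )
    manifest.write(out / "manifest.json")
    return manifest


def quantify_libraries(
    annotated: Mapping[str, pd.DataFrame], thresholds: Thresholds
) -> dict:
    """All per-library summaries used by the report."""
    summaries: Dict[str, LibrarySummary] = {}
    ratios: Dict[str, float] = {}
    profiles: Dict[str, pd.DataFrame] = {}
    tails: Dict[str, dict] = {}
    hists: Dict[str, pd.Series] = {}
    subclass: Dict[str, dict] = {}
    for lib_id in sorted(annotated):
        df = annotated[lib_id]
        counts = class_counts(df)
        summaries[lib_id] = normalize_rpm(counts, library_id=lib_id)
        try:
            ratios[lib_id] = ratio_21u_to_mirna(counts)
        except ValueError:
            ratios[lib_id] = float("nan")
        profiles[lib_id] = length_profiles(df, min_raw=thresholds.min_raw)
        tails[lib_id] = {}
        for cls in ("21U", "26G", "22G"):
            sub = df[df["rna_class"] == cls]
            if float(sub["weight"].sum()) > 0:
                t = tail_frequency(sub, cls)
                tails[lib_id][cls] = {
                    "U_TRIM": t.u_trim_pct, "A_TRIM": t.a_trim_pct, "OTHER": t.other_pct,
                }
            else:
                tails[lib_id][cls] = {"U_TRIM": 0.0, "A_TRIM": 0.0, "OTHER": 0.0}
        sirna = df[df["rna_class"].isin(SIRNA_CLASSES)]
        hists[lib_id] = length_distribution(sirna)
        sub26 = df[df["rna_class"] == "26G"]
        by_ago = sub26.groupby("ago_subclass")["weight"].sum().to_dict()
        entry = {
            "ERGO-1": float(by_ago.get("ERGO-1", 0.0)),
            "ALG-3/4": float(by_ago.get("ALG-3/4", 0.0)),
        }
        try:
            entry["ratio"] = subclass_ratio(sub26)
        except ValueError:
            entry["ratio"] = float("nan")
        subclass[lib_id] = entry
    return {
        "summaries": summaries, "ratios_21u_mirna": ratios, "profiles": profiles,
        "tails": tails, "sirna_length_hist": hists, "subclass_26g": subclass,
    }


def write_report(quant: dict, out_dir) -> None:
    """Figure-ready TSVs plus a consolidated JSON report.

    A pure function of the quantify outputs: re-running it changes
    nothing else.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    comp_rows = []
    for lib_id, summary in sorted(quant["summaries"].items()):
        for cls in sorted(set(summary.raw) | set(summary.rpm)):
            comp_rows.append({
                "library_id": lib_id, "rna_class": cls,
                "raw": summary.raw.get(cls, 0.0),
                "rpm": summary.rpm.get(cls, float("nan")),
            })
    pd.DataFrame(comp_rows, columns=["library_id", "rna_class", "raw", "rpm"]).to_csv(
        out / "class_composition.tsv", sep="\t", index=False
    )

    pd.DataFrame(
        [{"library_id": k, "ratio_21U_miRNA": v}
         for k, v in sorted(quant["ratios_21u_mirna"].items())]
    ).to_csv(out / "ratios_21u_mirna.tsv", sep="\t", index=False)

    prof_frames = []
    for lib_id, prof in sorted(quant["profiles"].items()):
        prof = prof.copy()
        prof.insert(0, "library_id", lib_id)
        prof_frames.append(prof)
    (pd.concat(prof_frames, ignore_index=True) if prof_frames else pd.DataFrame(
        columns=["library_id", "locus_id", "count_20", "count_21", "total_2021",
                 "fraction_20", "passes_filter"])
     ).to_csv(out / "length_profiles_21u.tsv", sep="\t", index=False)

    tail_rows = []
    for lib_id, by_cls in sorted(quant["tails"].items()):
        for cls, pct in sorted(by_cls.items()):
            tail_rows.append({"library_id": lib_id, "rna_class": cls, **pct})
    pd.DataFrame(tail_rows, columns=["library_id", "rna_class", "U_TRIM", "A_TRIM", "OTHER"]
                 ).to_csv(out / "tail_frequencies.tsv", sep="\t", index=False)

    hist_rows = []
    for lib_id, hist in sorted(quant["sirna_length_hist"].items()):
        for length, w in hist.items():
            hist_rows.append({"library_id": lib_id, "templated_length": length, "weight": w})
    pd.DataFrame(hist_rows, columns=["library_id", "templated_length", "weight"]).to_csv(
        out / "sirna_length_hist.tsv", sep="\t", index=False
    )

    pd.DataFrame(
        [{"library_id": k, **v} for k, v in sorted(quant["subclass_26g"].items())]
    ).to_csv(out / "subclass_26g.tsv", sep="\t", index=False)

    report = {
        "rpm": {k: v.rpm for k, v in sorted(quant["summaries"].items())},
        "conversion_factors": {
            k: v.conversion_factor for k, v in sorted(quant["summaries"].items())
        },
        "ratios_21u_mirna": quant["ratios_21u_mirna"],
        "tails": quant["tails"],
        "subclass_26g": quant["subclass_26g"],
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
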