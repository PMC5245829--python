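"""Synthetic stranded small-RNA libraries with a ground-truth manifest.

The generator emulates the structure of a directional Illumina small-RNA
library from a dinoflagellate-style experiment:

* planted miRNA/miRNA* duplex loci — a random guide strand plus the star
  strand that forms a duplex with 2-nt 3' overhangs, sequenced with strong
  guide/star count asymmetry (default 50:1);
* sense-strand mRNA degradation fragments that tile reference transcripts
  with >= 14-nt overlaps, so they assemble into long unidirectional contigs
  and are removed by the contig filter rather than the duplex test;
* contaminant reads copied verbatim from rRNA/tRNA/organelle reference
  entries, and polyA-bearing reads, each removed at its cleaning stage;
* a 3' sequencing adapter appended to every read.

Every read carries one manifest record (class, source, strand), so pipeline
stages can be scored for exact recovery. Generation is fully deterministic
given the seed. Sequence quality is constant (cleaning is not
quality-aware), and no sequencing-error or ligation-bias model is applied.

A small bundled reference fixture (fake rRNA/tRNA/organelle entries and five
synthetic transcripts, one LBP-like with a declared 3' UTR) ships with the
package so everything runs offline; it is synthetic data, not biological
sequence.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np

from .collapse_filter import CollapsedSet
from .duplex_search import pair_duplex
from .read_cleaning import TRUSEQ_SMALL_RNA_ADAPTER, has_polya
from .sequence_io import Read, ReferenceSet, read_fasta, revcomp, write_fastq

BASES = "ACGT"
_COMPL = {"A": "T", "C": "G", "G": "C", "T": "A"}

DEFAULT_LENGTH_WEIGHTS: dict[int, float] = {
    18: 1, 19: 2, 20: 4, 21: 8, 22: 40, 23: 8, 24: 4, 25: 2, 26: 1,
}  # majority (40/70) at 22 nt, the canonical Dicer-product length


@dataclass
class SimulationConfig:
    seed: int = 0
    n_mirna_loci: int = 20
    mirna_length_weights: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_WEIGHTS)
    )
    guide_star_ratio: float = 50.0
    star_depth: int = 5
    mirna_mutation_rate: float = 0.0
    n_fragments_per_transcript: int = 1000
    fragment_length_weights: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_WEIGHTS)
    )
    fragment_tile_step: int = 4
    contaminant_fractions: dict[str, float] = field(
        default_factory=lambda: {"rrna": 0.08, "trna": 0.05, "organelle": 0.04, "polya": 0.03}
    )
    adapter: str = TRUSEQ_SMALL_RNA_ADAPTER
    references: dict[str, ReferenceSet] | None = None  # default: bundled fixture

    def __post_init__(self) -> None:
        fr = self.contaminant_fractions
        if any(not (0.0 <= f <= 1.0) for f in fr.values()) or sum(fr.values()) > 1.0:
            raise ValueError("contaminant fractions must lie in [0,1] and sum to <= 1")
        if self.guide_star_ratio < 1.0:
            raise ValueError("guide_star_ratio must be >= 1")
        if self.fragment_tile_step < 1:
            raise ValueError("fragment_tile_step must be >= 1")


@dataclass(frozen=True)
class ManifestRecord:
    read_id: str
    klass: str  # mirna_guide | mirna_star | mrna_fragment | rrna | trna | organelle | polya
    source_id: str
    source_offset: int
    strand: str  # sense | antisense
    insert: str


@dataclass(frozen=True)
class LocusRecord:
    locus_id: str
    guide: str
    star: str
    guide_count: int
    star_count: int
    mismatches: int


@dataclass
class TruthManifest:
    reads: list[ManifestRecord] = field(default_factory=list)
    loci: list[LocusRecord] = field(default_factory=list)

    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for rec in self.reads:
            out[rec.klass] = out.get(rec.klass, 0) + 1
        return out

    def reads_of_class(self, klass: str) -> list[ManifestRecord]:
        return [r for r in self.reads if r.klass == klass]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["read_id", "class", "source_id", "source_offset", "strand", "insert"])
            for r in self.reads:
                w.writerow([r.read_id, r.klass, r.source_id, r.source_offset, r.strand, r.insert])


@dataclass
class LibraryBundle:
    reads: list[Read]
    manifest: TruthManifest
    references: dict[str, ReferenceSet]
    config: SimulationConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fastq(self.reads, outdir / "library.fastq")
        self.manifest.write_tsv(outdir / "manifest.tsv")
        from .sequence_io import write_fasta

        for name, ref in self.references.items():
            write_fasta(ref.records, outdir / f"{name}.fasta")


def bundled_references() -> dict[str, ReferenceSet]:
    """The packaged synthetic reference fixture (rRNA, tRNA, organelle,
    transcriptome), usable offline in tests and simulations."""
    pkg = resources.files("dinomir") / "data"
    out: dict[str, ReferenceSet] = {}
    for name in ("rrna", "trna", "organelle", "transcripts"):
        with resources.as_file(pkg / f"{name}.fasta") as path:
            out[name] = ReferenceSet.from_fasta(name, path)
    return out


def bundled_utr3() -> dict[str, int]:
    """Declared 3' UTR start offsets for the bundled transcripts."""
    pkg = resources.files("dinomir") / "data"
    out: dict[str, int] = {}
    with resources.as_file(pkg / "utr3.tsv") as path, open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if row and not row[0].startswith("#"):
                out[row[0]] = int(row[1])
    return out


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def _choose_length(rng: np.random.Generator, weights: dict[int, float]) -> int:
    lengths = sorted(weights)
    w = np.array([weights[l] for l in lengths], dtype=float)
    return int(rng.choice(lengths, p=w / w.sum()))


def make_duplex_locus(
    rng: np.random.Generator, length: int, mutation_budget: int = 0
) -> tuple[str, str]:
    """Random guide plus a star strand forming a valid 2-nt-overhang duplex.

    The star is the exact complement of the guide's pairing region plus a
    random 2-base overhang, then up to ``mutation_budget`` (<= 3) bases of
    its pairing region are substituted to non-complementary bases. The
    resulting pair always satisfies :func:`dinomir.duplex_search.pair_duplex`.
    """
    if not (18 <= length <= 26):
        raise ValueError("locus length must lie in 18..26")
    if not (0 <= mutation_budget <= 3):
        raise ValueError("mutation budget must lie in 0..3")
    guide = _random_seq(rng, length)
    star = revcomp(guide[:-2]) + _random_seq(rng, 2)
    if mutation_budget:
        positions = rng.choice(length - 2, size=mutation_budget, replace=False)
        star_list = list(star)
        for p in sorted(int(q) for q in positions):
            alternatives = [b for b in BASES if b != star_list[p]]
            star_list[p] = alternatives[int(rng.integers(0, 3))]
        star = "".join(star_list)
    assert pair_duplex(guide, star) is not None
    return guide, star


def allocate_largest_remainder(n: int, weights: dict[str, float]) -> dict[str, int]:
    """Split ``n`` items among keys proportionally, largest-remainder rounding."""
    total_w = sum(weights.values())
    if n == 0 or total_w == 0:
        return {k: 0 for k in weights}
    quotas = {k: n * w / total_w for k, w in weights.items()}
    counts = {k: int(q) for k, q in quotas.items()}
    short = n - sum(counts.values())
    by_remainder = sorted(weights, key=lambda k: (counts[k] - quotas[k], k))
    for k in by_remainder[:short]:
        counts[k] += 1
    return counts


def _kmer_set(seqs: Iterable[str], k: int = 14) -> set[str]:
    out: set[str] = set()
    for s in seqs:
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            out.add(kmer)
            out.add(revcomp(kmer))
    return out


def _shares_kmer(seq: str, kmers: set[str], k: int = 14) -> bool:
    return any(seq[i : i + k] in kmers for i in range(len(seq) - k + 1))


def generate_library(config: SimulationConfig) -> LibraryBundle:
    """Generate the full synthetic library and its truth manifest.

    Deterministic given ``config.seed``. Contaminant class counts follow the
    configured fractions of the total library size under largest-remainder
    rounding. Planted miRNA loci are rejection-sampled so they share no
    14-mer with the references, the transcripts or each other — otherwise a
    chance exact overlap would entangle them with the contig filter, which
    is not the condition being emulated.
    """
    rng = np.random.default_rng(config.seed)
    refs = config.references if config.references is not None else bundled_references()
    for klass in config.contaminant_fractions:
        if klass != "polya" and config.contaminant_fractions[klass] > 0 and klass not in refs:
            raise ValueError(f"contaminant class {klass!r} requested without a reference set")
    transcripts = refs.get("transcripts", ReferenceSet("transcripts", []))

    background_kmers = _kmer_set(
        [seq for ref in refs.values() for _, seq in ref.records], 14
    )

    # --- duplex loci ---------------------------------------------------
    loci: list[LocusRecord] = []
    guide_count = int(round(config.star_depth * config.guide_star_ratio))
    taken_kmers = set(background_kmers)
    for i in range(config.n_mirna_loci):
        length = _choose_length(rng, config.mirna_length_weights)
        budget = min(3, int(rng.binomial(length - 2, config.mirna_mutation_rate)))
        while True:
            guide, star = make_duplex_locus(rng, length, budget)
            if (
                not has_polya(guide, 6)
                and not has_polya(star, 6)
                and not _shares_kmer(guide, taken_kmers)
                and not _shares_kmer(star, taken_kmers)
            ):
                break
        taken_kmers |= _kmer_set([guide, star], 14)
        loci.append(
            LocusRecord(
                locus_id=f"locus{i:03d}",
                guide=guide,
                star=star,
                guide_count=guide_count,
                star_count=config.star_depth,
                mismatches=budget,
            )
        )

    inserts: list[tuple[str, str, str, int, str]] = []  # (class, insert, source, offset, strand)
    for loc in loci:
        for _ in range(loc.guide_count):
            inserts.append(("mirna_guide", loc.guide, loc.locus_id, 0, "sense"))
        for _ in range(loc.star_count):
            inserts.append(("mirna_star", loc.star, loc.locus_id, 0, "antisense"))

    # --- mRNA degradation fragments (sense strand, >=14-nt tiling) -----
    for tid, tseq in transcripts.records:
        positions = list(range(0, max(1, len(tseq) - 26 + 1), config.fragment_tile_step))
        frags: list[tuple[str, int]] = []
        for pos in positions:
            flen = _choose_length(rng, config.fragment_length_weights)
            flen = min(flen, len(tseq) - pos)
            if flen < 18:
                continue
            frags.append((tseq[pos : pos + flen], pos))
        if not frags:
            continue
        for k in range(config.n_fragments_per_transcript):
            frag, pos = frags[k % len(frags)]
            inserts.append(("mrna_fragment", frag, tid, pos, "sense"))

    # --- contaminants ---------------------------------------------------
    n_core = len(inserts)
    f_sum = sum(config.contaminant_fractions.values())
    if f_sum > 0 and n_core > 0:
        total = n_core / (1.0 - f_sum)
        n_contam = int(round(total * f_sum))
        counts = allocate_largest_remainder(n_contam, config.contaminant_fractions)
    else:
        counts = {k: 0 for k in config.contaminant_fractions}
    for klass in sorted(counts):
        for _ in range(counts[klass]):
            if klass == "polya":
                run = 7 + int(rng.integers(0, 3))
                flank = _random_seq(rng, 22 - min(run, 15))
                cut = int(rng.integers(0, len(flank) + 1))
                seq = flank[:cut] + "A" * run + flank[cut:]
                inserts.append(("polya", seq, "synthetic_polyA", 0, "sense"))
            else:
                rid, rseq = refs[klass].records[int(rng.integers(0, len(refs[klass].records)))]
                length = int(rng.integers(20, 27))
                length = min(length, len(rseq))
                off = int(rng.integers(0, len(rseq) - length + 1))
                sub = rseq[off : off + length]
                strand = "sense"
                if rng.random() < 0.5:
                    sub = revcomp(sub)
                    strand = "antisense"
                inserts.append((klass, sub, rid, off, strand))

    # --- emit reads -----------------------------------------------------
    order = rng.permutation(len(inserts))
    reads: list[Read] = []
    manifest = TruthManifest(loci=loci)
    for out_idx, ins_idx in enumerate(order):
        klass, insert, source, offset, strand = inserts[int(ins_idx)]
        rid = f"r{out_idx:06d}"
        seq = insert + config.adapter
        reads.append(Read(id=rid, seq=seq, qual="I" * len(seq)))
        manifest.reads.append(ManifestRecord(rid, klass, source, offset, strand, insert))
    return LibraryBundle(reads=reads, manifest=manifest, references=refs, config=config)


def evaluate_recovery(result, manifest: TruthManifest) -> dict[str, object]:
    """Score pipeline outputs against the generator's ground truth.

    ``result`` is a :class:`dinomir.cli_report.PipelineResult` (duck-typed:
    needs ``report`` with per-stage removed ids, ``filtered`` collapsed set,
    ``contig_result`` and ``duplex_pairs``). Returns per-class removal rates
    at the designated cascade stage, fragment-removal recall at the contig
    filter, the number of planted duplex reads the contig filter removed,
    duplex locus recall, candidate precision, guide/star ratio error, and
    the modal candidate length. An empty library yields
    ``{"undefined": True}``.
    """
    if not manifest.reads:
        return {"undefined": True}
    if result.report.initial_count != len(manifest.reads):
        raise ValueError(
            f"manifest has {len(manifest.reads)} reads but pipeline saw "
            f"{result.report.initial_count}"
        )
    metrics: dict[str, object] = {"undefined": False}

    stage_for_class = {"rrna": "rRNA removal", "trna": "tRNA removal",
                       "polya": "polyA removal", "organelle": "Organelle RNA cleaning"}
    removed_by_stage = result.report.removed_ids
    for klass, stage_prefix in stage_for_class.items():
        planted = {r.read_id for r in manifest.reads_of_class(klass)}
        if not planted:
            continue
        stage_removed: set[str] = set()
        for name, ids in removed_by_stage.items():
            if name.startswith(stage_prefix):
                stage_removed |= ids
        metrics[f"{klass}_stage_removal_rate"] = len(planted & stage_removed) / len(planted)

    # contig-filter scoring works on sequences of the min-count-filtered set
    frag_seqs = {r.insert for r in manifest.reads_of_class("mrna_fragment")}
    mirna_seqs = {loc.guide for loc in manifest.loci} | {loc.star for loc in manifest.loci}
    id_to_seq = {(cr.id or cr.seq): cr.seq for cr in result.filtered.reads}
    removed_seqs = {id_to_seq[i] for i in result.contig_result.removed_read_ids if i in id_to_seq}
    frag_present = frag_seqs & set(id_to_seq.values())
    if frag_present:
        metrics["fragment_removal_recall"] = len(frag_present & removed_seqs) / len(frag_present)
    metrics["duplex_reads_removed_by_contig_filter"] = len(mirna_seqs & removed_seqs)

    pair_seqs = {frozenset((p.read_a.seq, p.read_b.seq)) for p in result.duplex_pairs}
    recovered = [
        loc for loc in manifest.loci if frozenset((loc.guide, loc.star)) in pair_seqs
    ]
    metrics["duplex_recall"] = len(recovered) / len(manifest.loci) if manifest.loci else None
    mutation_free = [loc for loc in manifest.loci if loc.mismatches == 0]
    if mutation_free:
        metrics["duplex_recall_mutation_free"] = sum(
            1 for loc in mutation_free if frozenset((loc.guide, loc.star)) in pair_seqs
        ) / len(mutation_free)

    candidate_seqs = {s for p in result.duplex_pairs for s in (p.read_a.seq, p.read_b.seq)}
    if candidate_seqs:
        metrics["candidate_precision"] = len(candidate_seqs & mirna_seqs) / len(candidate_seqs)
        lengths = sorted(len(s) for s in candidate_seqs)
        from collections import Counter

        metrics["modal_candidate_length"] = Counter(lengths).most_common(1)[0][0]

    by_seq = {cr.seq: cr.count for cr in result.filtered.reads}
    ratio_errors = []
    for loc in recovered:
        g, s = by_seq.get(loc.guide), by_seq.get(loc.star)
        if g and s:
            ratio_errors.append(abs((g / s) - (loc.guide_count / loc.star_count))
                                / (loc.guide_count / loc.star_count))
    if ratio_errors:
        metrics["guide_star_ratio_error"] = float(np.mean(ratio_errors))
    return metrics
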