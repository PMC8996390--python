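"""Synthetic inputs with known ground truth for every pipeline stage.

Every generator is a pure function of its parameters and an integer seed:

* random genomes with i.i.d. bases at a chosen GC content,
* PAM sites planted on either strand (minus-strand sites appear as the
  reverse-complement pattern, e.g. CCN for NGG, on the written sequence),
* variant tables with an exact planted in-window fraction,
* amplicon read sets with planted precise/indel/WT proportions and uniform
  per-base substitution error,
* run-off reads terminating at planted cut offsets, with an optional
  untemplated terminal A (the polymerase A-tailing artifact).

Class/offset counts use exact largest-remainder partitioning by default so
planted truth is recovered integer-exactly; multinomial sampling is offered
where sampling noise is wanted.  Planting can create incidental extra PAM
occurrences, so truth tables guarantee "planted is a subset of found", and
variant placement always uses a post-plant scan, not the plant list.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._seq import IUPAC_SETS, revcomp
from .coverage import VariantRecord
from .editor_model import EditorProfile
from .errors import PlantingError, SimulationError
from .pegrna_design import EditSpec, apply_edit
from .site_scanner import scan_contig

__all__ = [
    "SimulationManifest",
    "make_genome",
    "plant_sites",
    "make_variant_table",
    "make_amplicon_reads",
    "make_runoff_reads",
    "exact_partition",
    "write_fasta",
    "write_fastq",
    "write_vcf",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimulationManifest:
    """Parameters and ground truth of one simulation; JSON-serialisable."""

    seed: int
    genome: dict = field(default_factory=dict)
    planted_sites: list = field(default_factory=list)
    variant_truth: list = field(default_factory=list)
    amplicon_truth: dict = field(default_factory=dict)
    runoff_truth: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.__dict__, indent=2, default=str)
        if path is not None:
            Path(path).write_text(text)
        return text


def exact_partition(n: int, proportions: Sequence[float]) -> list[int]:
    """Split n into integer counts matching proportions (largest remainder,
    ties broken by list order).  Counts always sum to n."""
    raw = [n * p for p in proportions]
    counts = [int(x) for x in raw]
    remainder = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


# ---------------------------------------------------------------------------
# Genomes and planted sites
# ---------------------------------------------------------------------------

def make_genome(
    n_contigs: int = 1,
    lengths: int | Sequence[int] = 5000,
    gc: float = 0.41,
    seed: int = 0,
) -> tuple[dict[str, str], dict]:
    """Random genome with i.i.d. bases at GC fraction ``gc``.

    Returns ``(genome, manifest_section)``; deterministic under ``seed``.
    The default GC of 0.41 mirrors the human genome average.
    """
    if not (0 < gc < 1):
        raise SimulationError(f"gc must be in (0, 1), got {gc}")
    if isinstance(lengths, int):
        lengths = [lengths] * n_contigs
    if len(lengths) != n_contigs:
        raise SimulationError("lengths must match n_contigs")
    if any(l < 100 for l in lengths):
        raise SimulationError("contig lengths must be >= 100")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    genome = {}
    for i, length in enumerate(lengths, start=1):
        bases = rng.choice(_BASES, size=length, p=probs)
        genome[f"contig_{i}"] = bases.tobytes().decode()
    manifest = {"n_contigs": n_contigs, "lengths": list(lengths), "gc": gc, "seed": seed}
    return genome, manifest


def _concretize_pam(pattern: str, rng: np.random.Generator) -> str:
    return "".join(
        c if len(IUPAC_SETS[c]) == 1 else IUPAC_SETS[c][rng.integers(len(IUPAC_SETS[c]))]
        for c in pattern
    )


def plant_sites(
    genome: Mapping[str, str],
    profile: EditorProfile,
    n_sites: int,
    min_spacing: int = 0,
    seed: int = 0,
    strands: Sequence[str] = ("+", "-"),
) -> tuple[dict[str, str], list[dict]]:
    """Write concrete PAM occurrences into a genome at random loci.

    Written PAM intervals never overlap each other, and per-contig PAM
    starts are pairwise >= ``min_spacing`` apart, so planted sites are never
    destroyed by later plants.  Raises :class:`PlantingError` (with the
    achieved count) when placement fails.  Returns the modified genome and
    a truth table [{contig, pam_start, strand, editor}, ...].
    """
    rng = np.random.default_rng(seed)
    seqs = {c: list(s.upper()) for c, s in genome.items()}
    contigs = list(seqs)
    weights = np.array([len(seqs[c]) for c in contigs], dtype=float)
    weights /= weights.sum()
    plen = profile.pam.length
    span_5p = profile.protospacer_len  # bases needed 5' of a '+' PAM
    written: dict[str, list[tuple[int, int]]] = {c: [] for c in contigs}
    pam_starts: dict[str, list[int]] = {c: [] for c in contigs}
    truth: list[dict] = []
    attempts_left = max(200 * n_sites, 1000)
    while len(truth) < n_sites and attempts_left > 0:
        attempts_left -= 1
        contig = contigs[rng.choice(len(contigs), p=weights)]
        L = len(seqs[contig])
        strand = strands[rng.integers(len(strands))]
        if strand == "+":
            lo, hi = span_5p, L - plen
        else:
            lo, hi = 0, L - plen - span_5p
        if hi <= lo:
            continue
        p = int(rng.integers(lo, hi))
        if any(p < e and p + plen > s for s, e in written[contig]):
            continue
        if min_spacing and any(abs(p - q) < min_spacing for q in pam_starts[contig]):
            continue
        concrete = _concretize_pam(profile.pam.pattern, rng)
        block = concrete if strand == "+" else revcomp(concrete)
        seqs[contig][p : p + plen] = list(block)
        written[contig].append((p, p + plen))
        pam_starts[contig].append(p)
        truth.append(
            {"contig": contig, "pam_start": p, "strand": strand, "editor": profile.name}
        )
    if len(truth) < n_sites:
        raise PlantingError(
            f"could only place {len(truth)}/{n_sites} sites with "
            f"min_spacing={min_spacing}",
            achieved=len(truth),
        )
    return {c: "".join(s) for c, s in seqs.items()}, truth


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------

def make_variant_table(
    genome: Mapping[str, str],
    profiles: Sequence[EditorProfile] | EditorProfile,
    n_snps: int,
    frac_in_window: float,
    seed: int = 0,
) -> tuple[list[VariantRecord], list[dict]]:
    """SNVs with an exact planted in-window fraction for the stated editor(s).

    Exactly ``round(n_snps * frac_in_window)`` SNVs are placed uniformly (no
    replacement) inside the union of editable windows found by a post-plant
    scan; the remainder are placed strictly outside all windows.  Reference
    alleles match the genome; alt != ref.  Raises
    :class:`SimulationError` when a side has too few eligible positions.
    """
    if isinstance(profiles, EditorProfile):
        profiles = [profiles]
    if not (0 <= frac_in_window <= 1):
        raise SimulationError("frac_in_window must be in [0, 1]")
    rng = np.random.default_rng(seed)
    in_window: list[tuple[str, int]] = []
    out_window: list[tuple[str, int]] = []
    for contig, seq in genome.items():
        windows: set[int] = set()
        for profile in profiles:
            for site in scan_contig(seq, contig, profile):
                windows.update(site.editable_positions)
        su = seq.upper()
        for pos in range(len(seq)):
            if su[pos] == "N":
                continue
            (in_window if pos in windows else out_window).append((contig, pos))
    n_in = round(n_snps * frac_in_window)
    n_out = n_snps - n_in
    if n_in > len(in_window):
        raise SimulationError(
            f"need {n_in} in-window positions, only {len(in_window)} available"
        )
    if n_out > len(out_window):
        raise SimulationError(
            f"need {n_out} out-of-window positions, only {len(out_window)} available"
        )
    chosen = [
        (pos, True)
        for pos in (in_window[i] for i in rng.choice(len(in_window), n_in, replace=False))
    ] if n_in else []
    chosen += [
        (pos, False)
        for pos in (out_window[i] for i in rng.choice(len(out_window), n_out, replace=False))
    ] if n_out else []
    rng.shuffle(chosen)
    variants: list[VariantRecord] = []
    truth: list[dict] = []
    for i, ((contig, pos), flag) in enumerate(chosen, start=1):
        ref = genome[contig][pos].upper()
        alts = [b for b in "ACGT" if b != ref]
        alt = alts[rng.integers(3)]
        variants.append(
            VariantRecord(contig=contig, pos=pos + 1, ref=ref, alt=alt, id=f"snv_{i}")
        )
        truth.append(
            {"id": f"snv_{i}", "contig": contig, "pos": pos + 1, "in_window": flag}
        )
    return variants, truth


# ---------------------------------------------------------------------------
# Amplicon reads
# ---------------------------------------------------------------------------

def _random_indel_allele(
    wt: str, edited: str, locus: int, rng: np.random.Generator
) -> str:
    """Random 1-3 nt deletion or insertion at the edit locus; resampled if it
    happens to reproduce the WT or precisely edited amplicon."""
    for _ in range(50):
        size = int(rng.integers(1, 4))
        if rng.random() < 0.5 and locus + size <= len(wt):
            allele = wt[:locus] + wt[locus + size :]
        else:
            ins = "".join(_BASES[rng.integers(4)].decode() for _ in range(size))
            allele = wt[:locus] + ins + wt[locus:]
        if allele != wt and allele != edited:
            return allele
    raise SimulationError("could not generate a distinct indel allele")


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(len(choices))]
    return arr.tobytes().decode()


def make_amplicon_reads(
    wt_amplicon: str,
    edit: EditSpec,
    proportions: Mapping[str, float],
    n_reads: int,
    per_base_error: float = 0.0,
    read_len: int | None = None,
    seed: int = 0,
    mode: str = "exact",
) -> tuple[list[tuple[str, str, str]], dict]:
    """Amplicon reads drawn from precise / indel / wt allele classes.

    ``proportions`` maps {"precise", "indel", "wt"} to fractions summing to
    1 (+- 1e-9).  ``mode`` 'exact' partitions class counts deterministically
    (largest remainder); 'multinomial' samples them.  Reads are the first
    ``read_len`` bases of the allele (full allele when None), with uniform
    substitution errors at ``per_base_error`` and constant Q40 quality.

    Returns ``(reads, truth)`` with reads as (id, sequence, quality) and
    truth holding per-class counts and per-read classes.
    """
    wt = wt_amplicon.upper()
    keys = ("precise", "indel", "wt")
    if set(proportions) - set(keys):
        raise SimulationError(f"proportions keys must be subset of {keys}")
    props = [float(proportions.get(k, 0.0)) for k in keys]
    if any(p < 0 for p in props) or abs(sum(props) - 1.0) > 1e-9:
        raise SimulationError(f"proportions must be >= 0 and sum to 1, got {props}")
    if n_reads < 1:
        raise SimulationError("n_reads must be >= 1")
    if not (0 <= per_base_error < 1):
        raise SimulationError("per_base_error must be in [0, 1)")
    rng = np.random.default_rng(seed)
    edited = apply_edit(wt, edit)
    locus = edit.start
    if mode == "exact":
        counts = exact_partition(n_reads, props)
    elif mode == "multinomial":
        counts = list(rng.multinomial(n_reads, props))
    else:
        raise SimulationError(f"mode must be 'exact' or 'multinomial', got {mode!r}")

    reads: list[tuple[str, str, str]] = []
    classes: list[str] = []
    for cls, n in zip(keys, counts):
        for _ in range(n):
            if cls == "precise":
                allele = edited
            elif cls == "wt":
                allele = wt
            else:
                allele = _random_indel_allele(wt, edited, locus, rng)
            seq = allele[:read_len] if read_len else allele
            seq = _add_errors(seq, per_base_error, rng)
            classes.append(cls)
            reads.append((cls, seq))  # id filled after shuffling
    order = rng.permutation(len(reads))
    shuffled = []
    per_read = []
    for new_i, i in enumerate(order):
        cls, seq = reads[i]
        read_id = f"read_{new_i:06d}|{cls}"
        shuffled.append((read_id, seq, "I" * len(seq)))
        per_read.append({"id": read_id, "class": cls})
    truth = {
        "counts": dict(zip(keys, counts)),
        "proportions": dict(zip(keys, props)),
        "per_base_error": per_base_error,
        "mode": mode,
        "reads": per_read,
    }
    return shuffled, truth


# ---------------------------------------------------------------------------
# Run-off reads
# ---------------------------------------------------------------------------

def make_runoff_reads(
    reference: str,
    pam_start: int,
    offset_distribution: Mapping[int, float],
    a_tail_prob: float = 1.0,
    n: int = 100,
    seed: int = 0,
    mode: str = "exact",
    anchor_start: int = 0,
) -> tuple[list[tuple[str, str]], dict]:
    """Run-off reads ending at cut gaps ``pam_start - offset``.

    Each read is the reference from ``anchor_start`` to the sampled cut gap,
    plus one terminal A with probability ``a_tail_prob``.  ``mode`` 'exact'
    partitions offset counts deterministically; 'sample' draws them.
    Offsets whose cut gap falls outside the reference raise.
    """
    reference = reference.upper()
    offsets = sorted(offset_distribution)
    probs = [float(offset_distribution[o]) for o in offsets]
    if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
        raise SimulationError("offset_distribution must be >= 0 and sum to 1")
    for o in offsets:
        gap = pam_start - o
        if not (anchor_start < gap <= len(reference)):
            raise SimulationError(
                f"offset {o} puts the cut gap at {gap}, outside the reference"
            )
    if not (0 <= a_tail_prob <= 1):
        raise SimulationError("a_tail_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if mode == "exact":
        counts = exact_partition(n, probs)
    elif mode == "sample":
        counts = list(rng.multinomial(n, probs))
    else:
        raise SimulationError(f"mode must be 'exact' or 'sample', got {mode!r}")
    reads: list[tuple[str, str]] = []
    truth_counts = dict(zip(offsets, counts))
    i = 0
    for offset, cnt in zip(offsets, counts):
        gap = pam_start - offset
        for _ in range(cnt):
            seq = reference[anchor_start:gap]
            tailed = rng.random() < a_tail_prob
            if tailed:
                seq += "A"
            reads.append((f"runoff_{i:05d}|off={offset}|A={int(tailed)}", seq))
            i += 1
    order = rng.permutation(len(reads))
    reads = [reads[j] for j in order]
    truth = {
        "offset_counts": truth_counts,
        "a_tail_prob": a_tail_prob,
        "pam_start": pam_start,
        "anchor_start": anchor_start,
        "mode": mode,
    }
    return reads, truth


# ---------------------------------------------------------------------------
# Writers (plain-text formats)
# ---------------------------------------------------------------------------

def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(reads: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read_id, seq, qual in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


def write_vcf(
    variants: Sequence[VariantRecord],
    contig_lengths: Mapping[str, int],
    path: str | Path,
) -> None:
    """Minimal VCFv4.2 text output (readable by pysam/bcftools)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=primewindow-synthetic\n")
        for contig, length in contig_lengths.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write(
            '##INFO=<ID=CLNSIG,Number=.,Type=String,Description="Clinical significance">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            info = f"CLNSIG={v.significance}" if v.significance else "."
            fh.write(
                f"{v.contig}\t{v.pos}\t{v.id or '.'}\t{v.ref}\t{v.alt}\t.\t.\t{info}\n"
            )
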