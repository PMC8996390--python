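"""Pathogenic-SNP coverage: intersect SNV positions with editable windows.

For a given editor profile, a variant is *targetable* iff its position lies
inside the editable window of at least one target site of that editor, on
either strand (an installed edit rewrites both strands, and minus-strand
PAMs — CCN for NGG — are scanned symmetrically).  The summary statistic is

    covered ratio (%) = targetable SNPs / total SNPs x 100
    uncovered ratio (%) = 100 - covered ratio

Each variant is counted once no matter how many sites cover it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .editor_model import EditorProfile
from .errors import CoverageError, VariantParseError
from .site_scanner import TargetSite, normalize_contig_name, scan_genome

__all__ = [
    "VariantRecord",
    "CoverageResult",
    "load_variants",
    "compute_coverage",
    "union_coverage",
    "coverage_report",
]

_BASES = {"A", "C", "G", "T"}


@dataclass(frozen=True)
class VariantRecord:
    """A single-nucleotide substitution; ``pos`` is 1-based (VCF convention)."""

    contig: str
    pos: int
    ref: str
    alt: str
    id: str | None = None
    significance: str | None = None

    def __post_init__(self) -> None:
        if self.pos <= 0:
            raise VariantParseError(f"variant position must be >= 1, got {self.pos}")
        if self.ref.upper() not in _BASES or self.alt.upper() not in _BASES:
            raise VariantParseError(
                f"ref/alt must be single bases ACGT, got {self.ref!r}>{self.alt!r}"
            )
        object.__setattr__(self, "ref", self.ref.upper())
        object.__setattr__(self, "alt", self.alt.upper())


@dataclass(frozen=True)
class CoverageResult:
    """Per-editor covered/uncovered SNP ratios with a per-contig breakdown."""

    editor: str
    total_snps: int
    targetable_snps: int
    per_contig: Mapping[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.total_snps <= 0:
            raise CoverageError("no variants after filtering")
        if not (0 <= self.targetable_snps <= self.total_snps):
            raise CoverageError(
                f"targetable_snps {self.targetable_snps} outside "
                f"[0, {self.total_snps}]"
            )

    @property
    def covered_ratio(self) -> float:
        return self.targetable_snps / self.total_snps * 100.0

    @property
    def uncovered_ratio(self) -> float:
        return 100.0 - self.covered_ratio

    def as_dict(self) -> dict:
        return {
            "editor": self.editor,
            "total_snps": self.total_snps,
            "targetable_snps": self.targetable_snps,
            "covered_ratio_pct": self.covered_ratio,
            "uncovered_ratio_pct": self.uncovered_ratio,
            "per_contig": {c: list(v) for c, v in self.per_contig.items()},
        }


# ---------------------------------------------------------------------------
# Variant input
# ---------------------------------------------------------------------------

def _is_snv(ref: str, alt: str) -> bool:
    return (
        len(ref) == 1 and len(alt) == 1
        and ref.upper() in _BASES and alt.upper() in _BASES
    )


def load_variants(
    path: str | Path,
    significance_filter: str | None = None,
    exclude_contigs: Iterable[str] = (),
) -> tuple[list[VariantRecord], dict[str, int]]:
    """Load single-nucleotide substitutions from a VCF or TSV.

    TSV requires columns chrom, pos, ref, alt (optional id, significance).
    Multiallelic VCF lines are split into per-alt records before filtering.
    Non-SNV records are skipped and counted; variants on excluded contigs
    (Y/MT dialects) are dropped when an exclusion set is given.  The
    significance filter is a plain case-insensitive substring match against
    the significance column / the CLNSIG INFO field.

    Returns ``(records, skipped)`` with skipped counts by reason.
    """
    path = Path(path)
    if not path.exists():
        raise VariantParseError(f"variant file not found: {path}")
    name = path.name.lower()
    if name.endswith((".vcf", ".vcf.gz", ".bcf")):
        return _load_vcf(path, significance_filter, exclude_contigs)
    return _load_tsv(path, significance_filter, exclude_contigs)


def _passes(
    contig: str,
    significance: str | None,
    significance_filter: str | None,
    excluded_norm: set[str],
    skipped: dict[str, int],
) -> bool:
    if normalize_contig_name(contig) in excluded_norm:
        skipped["excluded_contig"] += 1
        return False
    if significance_filter is not None:
        if significance is None or significance_filter.lower() not in significance.lower():
            skipped["significance"] += 1
            return False
    return True


def _load_vcf(path, significance_filter, exclude_contigs):
    import pysam

    excluded_norm = {normalize_contig_name(e) for e in exclude_contigs}
    skipped = {"non_snv": 0, "excluded_contig": 0, "significance": 0}
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            clnsig = rec.info.get("CLNSIG") if "CLNSIG" in rec.info else None
            if isinstance(clnsig, (tuple, list)):
                clnsig = ",".join(str(c) for c in clnsig)
            for alt in rec.alts or ():
                if not _is_snv(rec.ref or "", alt):
                    skipped["non_snv"] += 1
                    continue
                if not _passes(rec.contig, clnsig, significance_filter, excluded_norm, skipped):
                    continue
                records.append(
                    VariantRecord(
                        contig=rec.contig,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        id=rec.id,
                        significance=clnsig,
                    )
                )
    return records, skipped


def _load_tsv(path, significance_filter, exclude_contigs):
    excluded_norm = {normalize_contig_name(e) for e in exclude_contigs}
    skipped = {"non_snv": 0, "excluded_contig": 0, "significance": 0}
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except Exception as exc:
        raise VariantParseError(f"could not parse TSV {path}: {exc}") from exc
    missing = {"chrom", "pos", "ref", "alt"} - set(df.columns)
    if missing:
        raise VariantParseError(
            f"TSV {path} missing required columns: {sorted(missing)}"
        )
    records: list[VariantRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        row_d = row._asdict()
        try:
            pos = int(row_d["pos"])
        except (TypeError, ValueError):
            raise VariantParseError(f"non-integer pos {row_d['pos']!r}", line=i) from None
        if pos <= 0:
            raise VariantParseError(f"pos must be >= 1, got {pos}", line=i)
        ref, alt = str(row_d["ref"]), str(row_d["alt"])
        if not _is_snv(ref, alt):
            skipped["non_snv"] += 1
            continue
        sig = row_d.get("significance")
        sig = None if sig is None or (isinstance(sig, float) and math.isnan(sig)) else str(sig)
        if not _passes(str(row_d["chrom"]), sig, significance_filter, excluded_norm, skipped):
            continue
        records.append(
            VariantRecord(
                contig=str(row_d["chrom"]), pos=pos, ref=ref, alt=alt,
                id=row_d.get("id"), significance=sig,
            )
        )
    return records, skipped


# ---------------------------------------------------------------------------
# Coverage computation
# ---------------------------------------------------------------------------

def _dedup(variants: Sequence[VariantRecord], how: str) -> list[VariantRecord]:
    seen: set = set()
    out = []
    for v in variants:
        key = (v.contig, v.pos) if how == "position" else (v.contig, v.pos, v.ref, v.alt)
        if key not in seen:
            seen.add(key)
            out.append(v)
    return out


def compute_coverage(
    variants: Sequence[VariantRecord],
    sites: Iterable[TargetSite] | None = None,
    editor: str | EditorProfile | None = None,
    genome: Mapping[str, str] | str | Path | None = None,
    dedup: str = "record",
    exclude_contigs: Iterable[str] = (),
) -> CoverageResult:
    """Covered/uncovered ratio of a variant set for one editor.

    Either pass pre-scanned ``sites`` (optionally filtered to ``editor``),
    or a ``genome`` plus an :class:`EditorProfile` to scan on the fly.
    ``dedup`` is 'record' ((contig,pos,ref,alt) identity — distinct alt
    alleles at one position count as distinct SNPs) or 'position'.
    """
    if dedup not in {"record", "position"}:
        raise ValueError(f"dedup must be 'record' or 'position', got {dedup!r}")
    editor_name = editor.name if isinstance(editor, EditorProfile) else editor
    if sites is None:
        if genome is None or not isinstance(editor, EditorProfile):
            raise ValueError(
                "compute_coverage needs either sites=... or genome=... plus an "
                "EditorProfile as editor="
            )
        by_editor, _ = scan_genome(genome, [editor], exclude_contigs=exclude_contigs)
        sites = by_editor[editor.name]
    site_list = [
        s for s in sites if editor_name is None or s.editor == editor_name
    ]

    covered: dict[str, set[int]] = {}
    for s in site_list:
        covered.setdefault(s.contig, set()).update(s.editable_positions)

    kept = _dedup(list(variants), dedup)
    if not kept:
        raise CoverageError("no variants after filtering")
    per_contig: dict[str, list[int]] = {}
    n_targetable = 0
    for v in kept:
        tot_tar = per_contig.setdefault(v.contig, [0, 0])
        tot_tar[0] += 1
        if (v.pos - 1) in covered.get(v.contig, ()):  # pos is 1-based
            tot_tar[1] += 1
            n_targetable += 1
    return CoverageResult(
        editor=editor_name or (site_list[0].editor if site_list else "none"),
        total_snps=len(kept),
        targetable_snps=n_targetable,
        per_contig={c: (t[0], t[1]) for c, t in per_contig.items()},
    )


def union_coverage(
    variants: Sequence[VariantRecord],
    sites_by_editor: Mapping[str, Sequence[TargetSite]],
    dedup: str = "record",
    label: str = "union",
) -> CoverageResult:
    """Coverage of the union of several editors' windows (any editor covers)."""
    all_sites = [s for sites in sites_by_editor.values() for s in sites]
    result = compute_coverage(variants, sites=all_sites, editor=None, dedup=dedup)
    return CoverageResult(
        editor=label,
        total_snps=result.total_snps,
        targetable_snps=result.targetable_snps,
        per_contig=result.per_contig,
    )


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def coverage_report(
    results: Sequence[CoverageResult],
    out_dir: str | Path | None = None,
    chart: bool = False,
) -> tuple[pd.DataFrame, list[dict]]:
    """Tabulate coverage results; optionally write TSV/JSON and pie charts.

    The TSV shows ratios to 2 decimals; the JSON keeps full precision.
    """
    if not results:
        raise ValueError("coverage_report requires at least one result")
    payload = [r.as_dict() for r in results]
    df = pd.DataFrame(
        [
            {
                "editor": d["editor"],
                "total_snps": d["total_snps"],
                "targetable_snps": d["targetable_snps"],
                "covered_ratio_pct": round(d["covered_ratio_pct"], 2),
                "uncovered_ratio_pct": round(d["uncovered_ratio_pct"], 2),
            }
            for d in payload
        ]
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_dir / "coverage.tsv", sep="\t", index=False)
        (out_dir / "coverage.json").write_text(json.dumps(payload, indent=2))
        if chart:
            _pie_charts(results, out_dir)
    return df, payload


def _pie_charts(results: Sequence[CoverageResult], out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(results), figsize=(4 * len(results), 4))
    if len(results) == 1:
        axes = [axes]
    for ax, r in zip(axes, results):
        ax.pie(
            [r.covered_ratio, r.uncovered_ratio],
            labels=[f"covered {r.covered_ratio:.2f}%", f"uncovered {r.uncovered_ratio:.2f}%"],
            colors=["#4c72b0", "#dddddd"],
            startangle=90,
        )
        ax.set_title(r.editor)
    fig.tight_layout()
    fig.savefig(out_dir / "coverage_pie.png", dpi=150)
    plt.close(fig)
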