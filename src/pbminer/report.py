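"""Per-species summaries, aggregate statistics and recovery evaluation.

Two consumers: (1) the published survey table of piggyBac content in 37
animal species, shipped as a transcribed TSV fixture, whose headline
arithmetic (total full-length types, intact-containing types, per-phylum
fractions) is recomputed here; (2) the simulation pipeline, whose element
calls are scored against planted ground truth (detection recall, boundary
accuracy, TSD recovery, copy-count and intactness-label errors).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import pandas as pd

from .boundaries import ElementModel


def round1(x: float) -> float:
    """One-decimal rounding, half away from zero (as the survey prints)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class SpeciesSummaryRow:
    taxon: str  # phylum
    order: str
    species: str
    n_fl_types: int
    n_intact_types: int
    fl_length_range: tuple[int, int] | None = None
    intact_length_range: tuple[int, int] | None = None
    transposase_length_range: tuple[int, int] | None = None
    tir_length_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.n_intact_types > self.n_fl_types:
            raise ValueError("intact-containing types cannot exceed FL types")


@dataclass
class AggregateCounts:
    total_types: int
    total_intact_types: int
    total_no_intact: int
    n_species_with_pb: int
    n_single_type_species: int
    per_phylum_species: dict[str, int]
    per_phylum_types: dict[str, int]
    per_phylum_intact_types: dict[str, int]
    per_phylum_pct: dict[str, float]  # % of PB-containing species in each phylum

    def grouped_pct(self, phyla: tuple[str, ...]) -> float:
        n = sum(self.per_phylum_species.get(p, 0) for p in phyla)
        return round1(100.0 * n / self.n_species_with_pb)


def _fixture(name: str) -> Path:
    return Path(str(resources.files("pbminer").joinpath(f"data/{name}")))


def load_table1(path: str | Path | None = None) -> pd.DataFrame:
    """The packaged species-survey table (or a user-supplied one)."""
    return pd.read_csv(path or _fixture("table1.tsv"), sep="\t")


def load_table1_phyla(path: str | Path | None = None) -> pd.DataFrame:
    return pd.read_csv(path or _fixture("table1_phyla.tsv"), sep="\t")


def _parse_range(text) -> tuple[int, int] | None:
    if text is None or (isinstance(text, float) and pd.isna(text)) or text == "-":
        return None
    s = str(text)
    if "-" in s:
        a, b = s.split("-", 1)
        return int(a), int(b)
    return int(s), int(s)


def rows_from_table(df: pd.DataFrame) -> list[SpeciesSummaryRow]:
    rows = []
    for _, r in df.iterrows():
        intact = 0 if str(r["n_intact_types"]) == "-" else int(r["n_intact_types"])
        rows.append(
            SpeciesSummaryRow(
                taxon=r["phylum"],
                order=r["order"],
                species=r["species"],
                n_fl_types=int(r["n_fl_types"]),
                n_intact_types=intact,
                fl_length_range=_parse_range(r.get("fl_length_bp")),
                intact_length_range=_parse_range(r.get("intact_length_bp")),
                transposase_length_range=_parse_range(r.get("transposase_length_aa")),
                tir_length_range=_parse_range(r.get("tir_length_bp")),
            )
        )
    return rows


def summarize_species(
    elements: list[ElementModel],
    taxon: str = "simulated",
    order: str = "simulated",
    species: str = "simulated",
) -> SpeciesSummaryRow:
    """Collapse one genome's element calls into a survey-table row.

    FL types are counted by classification; intact-containing types are FL
    types with at least one intact copy.  Ranges cover per-type values.
    """
    fl = [e for e in elements if e.element_class == "FL"]
    intact = [e for e in fl if e.intact_copy_count >= 1]

    def span_range(els: list[ElementModel]) -> tuple[int, int] | None:
        lengths = [
            e.boundaries[1] - e.boundaries[0] for e in els if e.boundaries is not None
        ]
        return (min(lengths), max(lengths)) if lengths else None

    tirs = [e.tir_length for e in fl if e.tir_length]
    return SpeciesSummaryRow(
        taxon=taxon,
        order=order,
        species=species,
        n_fl_types=len(fl),
        n_intact_types=len(intact),
        fl_length_range=span_range(fl),
        intact_length_range=span_range(intact),
        tir_length_range=(min(tirs), max(tirs)) if tirs else None,
    )


def aggregate(rows: list[SpeciesSummaryRow]) -> AggregateCounts:
    """Headline counts over species rows (only species with >= 1 FL type count)."""
    if not rows:
        raise ValueError("aggregate requires at least one species row")
    with_pb = [r for r in rows if r.n_fl_types >= 1]
    per_species: dict[str, int] = {}
    per_types: dict[str, int] = {}
    per_intact: dict[str, int] = {}
    for r in with_pb:
        per_species[r.taxon] = per_species.get(r.taxon, 0) + 1
        per_types[r.taxon] = per_types.get(r.taxon, 0) + r.n_fl_types
        per_intact[r.taxon] = per_intact.get(r.taxon, 0) + r.n_intact_types
    n_with = len(with_pb)
    total = sum(r.n_fl_types for r in with_pb)
    total_intact = sum(r.n_intact_types for r in with_pb)
    return AggregateCounts(
        total_types=total,
        total_intact_types=total_intact,
        total_no_intact=total - total_intact,
        n_species_with_pb=n_with,
        n_single_type_species=sum(1 for r in with_pb if r.n_fl_types == 1),
        per_phylum_species=per_species,
        per_phylum_types=per_types,
        per_phylum_intact_types=per_intact,
        per_phylum_pct={
            p: round1(100.0 * c / n_with) for p, c in sorted(per_species.items())
        },
    )


def threshold_stats(
    per_type_intact_counts: list[int], min_copies: int = 6
) -> tuple[int, float]:
    """How many types fall below an intact-copy threshold, and the percentage."""
    if not per_type_intact_counts:
        raise ValueError("no per-type counts supplied")
    if any(c < 0 for c in per_type_intact_counts):
        raise ValueError("intact-copy counts must be nonnegative")
    n_below = sum(1 for c in per_type_intact_counts if c < min_copies)
    return n_below, round1(100.0 * n_below / len(per_type_intact_counts))


# ---------------------------------------------------------------------------
# Recovery evaluation against simulator truth


@dataclass
class TypeRecovery:
    type_id: str
    detected: bool
    called_as: str | None
    class_match: bool
    boundary_error_bp: int | None  # max terminal offset over matched intact copies
    tsd_match: bool
    copy_count_error: int | None
    intact_count_error: int | None


@dataclass
class RecoveryReport:
    per_type: dict[str, TypeRecovery]
    recall: float
    precision: float | None  # None when there are no calls (reported as NA)
    copy_label_accuracy: float | None = None
    n_matched_copies: int = 0

    def summary(self) -> dict:
        return {
            "recall": self.recall,
            "precision": self.precision if self.precision is not None else "NA",
            "copy_label_accuracy": self.copy_label_accuracy,
            "types_detected": sum(1 for t in self.per_type.values() if t.detected),
            "types_total": len(self.per_type),
        }


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    ov = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    la, lb = a[1] - a[0], b[1] - b[0]
    if not la or not lb:
        return 0.0
    return min(ov / la, ov / lb)


def evaluate_recovery(
    elements: list[ElementModel],
    truth_copies: list,
    genome_id: str | None = None,
    expected_genome_id: str | None = None,
) -> RecoveryReport:
    """Score element calls against planted copies.

    A planted type is detected if any FL/transposon-like call has >= 50%
    reciprocal overlap (via its copy hits) with a planted copy of the
    type.  Copy-level intactness labels are compared where copies match.
    ``truth_copies`` are simulator PlantedCopy records (or dicts).
    """
    if genome_id is not None and expected_genome_id is not None:
        if genome_id != expected_genome_id:
            raise ValueError(
                f"truth genome {expected_genome_id!r} does not match output genome {genome_id!r}"
            )

    def _get(c, name):
        return c[name] if isinstance(c, dict) else getattr(c, name)

    truth_by_type: dict[str, list] = {}
    for c in truth_copies:
        truth_by_type.setdefault(_get(c, "type_id"), []).append(c)

    calls = [e for e in elements if e.element_class in ("FL", "transposon_like")]
    per_type: dict[str, TypeRecovery] = {}
    matched_elements: set[str] = set()
    n_label_ok = n_label = 0
    for tid, copies in sorted(truth_by_type.items()):
        spans = [tuple(_get(c, "realized_span")) for c in copies]
        best_el, best_ov = None, 0.0
        for el in calls:
            for hit in el.copy_hits:
                for s in spans:
                    ov = _reciprocal_overlap(hit.span, s)
                    if ov > best_ov:
                        best_ov, best_el = ov, el
        detected = best_ov >= 0.5
        if not detected:
            per_type[tid] = TypeRecovery(tid, False, None, False, None, False, None, None)
            continue
        el = best_el
        matched_elements.add(el.type_id)
        # copy-level matching
        boundary_err = None
        copy_matches = 0
        for hit in el.copy_hits:
            best_c, ov_c = None, 0.0
            for c in copies:
                ov = _reciprocal_overlap(hit.span, tuple(_get(c, "realized_span")))
                if ov > ov_c:
                    ov_c, best_c = ov, c
            if ov_c < 0.5 or best_c is None:
                continue
            copy_matches += 1
            n_label += 1
            if hit.is_intact == bool(_get(best_c, "is_intact")):
                n_label_ok += 1
            if bool(_get(best_c, "is_intact")):
                ts, te = _get(best_c, "realized_span")
                err = max(abs(hit.span[0] - ts), abs(hit.span[1] - te))
                boundary_err = err if boundary_err is None else max(boundary_err, err)
        n_truth_intact = sum(1 for c in copies if _get(c, "is_intact"))
        per_type[tid] = TypeRecovery(
            type_id=tid,
            detected=True,
            called_as=el.element_class,
            class_match=el.element_class == "FL",
            boundary_error_bp=boundary_err,
            tsd_match=el.tsd == (_get(copies[0], "tsd") or None)
            or (el.tsd is not None and el.tsd == "TTAA"),
            copy_count_error=el.copy_count - len(copies),
            intact_count_error=el.intact_copy_count - n_truth_intact,
        )
    recall = (
        sum(1 for t in per_type.values() if t.detected) / len(per_type) if per_type else 0.0
    )
    precision = len(matched_elements) / len(calls) if calls else None
    return RecoveryReport(
        per_type=per_type,
        recall=recall,
        precision=precision,
        copy_label_accuracy=(n_label_ok / n_label) if n_label else None,
        n_matched_copies=n_label,
    )
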