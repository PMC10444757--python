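"""Opsin spectral tuning-site analysis in bovine rhodopsin numbering.

Ciliary opsin residue positions are conventionally reported relative to
bovine rhodopsin (RH1): a query opsin is globally aligned to the 348-residue
bovine sequence and each of its residues inherits the bovine position it
pairs with.  Spectral tuning sites — positions where substitutions are known
from site-directed mutagenesis to shift the pigment's peak absorbance
(lambda_max) — can then be compared between species, and a lambda_max for an
unmeasured opsin estimated as

    anchor lambda_max  +  sum of the known shift intervals of the
                          substitutions separating it from the anchor,

where the anchor is a close homolog with a measured lambda_max.  Because the
published shifts are intervals (e.g. "0 to -3 nm"), the estimate is an
interval; the point estimate keeps the anchor value whenever zero net shift
is consistent with the data, and falls back to the interval midpoint
otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "AMINO_ACIDS",
    "NumberedSequence",
    "SubstitutionRecord",
    "TuningSiteTable",
    "TuningComparison",
    "LambdaMaxEstimate",
    "bovine_reference",
    "map_to_bovine",
    "compare_tuning_sites",
    "estimate_lambda_max",
    "read_fasta",
    "write_fasta",
]

log = logging.getLogger(__name__)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: lambda_max range of all known vertebrate SWS1 opsins, nm.
SWS1_RANGE_NM = (360.0, 440.0)

_ANCHOR_RANGE = (330.0, 650.0)


def _validate_protein(residues: str, label: str) -> str:
    residues = residues.upper().replace("*", "")
    bad = sorted(set(residues) - AMINO_ACIDS)
    if bad:
        raise ValueError(
            f"{label}: non-amino-acid characters {''.join(bad)!r}"
        )
    if not residues:
        raise ValueError(f"{label}: empty sequence")
    return residues


def bovine_reference() -> tuple[str, str]:
    """(id, residues) of the packaged bovine RH1 numbering standard."""
    ref = resources.files("dermalight.data").joinpath("bovine_rh1.fasta")
    with resources.as_file(ref) as path:
        record = next(SeqIO.parse(str(path), "fasta"))
    return record.id, str(record.seq)


@dataclass(frozen=True)
class NumberedSequence:
    """An amino-acid sequence with per-residue bovine RH1 positions.

    ``bovine_map[i]`` is the bovine position (1-based) of residue ``i`` of
    ``residues``, or ``None`` where the residue falls in an insertion
    relative to bovine RH1.
    """

    id: str
    residues: str
    bovine_map: tuple[Optional[int], ...]

    def __post_init__(self) -> None:
        if len(self.residues) != len(self.bovine_map):
            raise ValueError("bovine_map length must match sequence length")
        mapped = [p for p in self.bovine_map if p is not None]
        if any(b <= a for a, b in zip(mapped, mapped[1:])):
            raise ValueError("bovine positions must be strictly increasing")

    def residue_at(self, bovine_position: int) -> Optional[str]:
        """Residue aligned to a bovine position, or None if gapped/unmapped."""
        for res, pos in zip(self.residues, self.bovine_map):
            if pos == bovine_position:
                return res
        return None


def map_to_bovine(
    seq: str,
    bovine: Optional[str] = None,
    seq_id: str = "query",
) -> NumberedSequence:
    """Globally align an opsin sequence to bovine RH1 and number its residues.

    Needleman-Wunsch global alignment under BLOSUM62 with gap open 10 and
    gap extend 1 (score units).  Ciliary opsins are conserved enough that
    any standard global scheme yields the same residue numbering; ties are
    broken deterministically by taking the aligner's first optimal path.
    """
    residues = _validate_protein(seq, seq_id)
    if bovine is None:
        _, bovine = bovine_reference()
    bovine = _validate_protein(bovine, "bovine reference")

    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    alignment = aligner.align(bovine, residues)[0]

    bovine_map: list[Optional[int]] = [None] * len(residues)
    for (t0, t1), (q0, q1) in zip(*alignment.aligned):
        for offset in range(t1 - t0):
            bovine_map[q0 + offset] = t0 + offset + 1  # bovine numbering is 1-based
    return NumberedSequence(seq_id, residues, tuple(bovine_map))


@dataclass(frozen=True)
class SubstitutionRecord:
    """One amino-acid difference at a tuning site, e.g. ``S97C``."""

    site: int
    ref_residue: str
    alt_residue: str

    @property
    def notation(self) -> str:
        return f"{self.ref_residue}{self.site}{self.alt_residue}"

    def __str__(self) -> str:
        return self.notation


@dataclass(frozen=True)
class TuningSiteTable:
    """Tuning sites plus known per-substitution lambda_max shift intervals."""

    sites: tuple[int, ...]
    shifts: dict[tuple[int, str, str], tuple[float, float]]
    default_halfwidth_nm: float = 3.0

    def __post_init__(self) -> None:
        if len(set(self.sites)) != len(self.sites):
            raise ValueError("tuning sites must be unique")
        if any(not (1 <= s <= 348) for s in self.sites):
            raise ValueError("tuning sites must lie within bovine RH1 (1-348)")
        for key, (lo, hi) in self.shifts.items():
            if lo > hi:
                raise ValueError(f"shift interval for {key} has low > high")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "TuningSiteTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        shifts = {
            (int(e["site"]), str(e["from"]), str(e["to"])):
                (float(e["low"]), float(e["high"]))
            for e in raw.get("shifts", [])
        }
        return cls(
            sites=tuple(int(s) for s in raw["sites"]),
            shifts=shifts,
            default_halfwidth_nm=float(raw.get("default_shift_halfwidth_nm", 3.0)),
        )

    @classmethod
    def default(cls) -> "TuningSiteTable":
        ref = resources.files("dermalight.data").joinpath("sws1_tuning_sites.yaml")
        with resources.as_file(ref) as path:
            return cls.from_yaml(path)

    def shift_interval(self, record: SubstitutionRecord) -> tuple[float, float, bool]:
        """(low, high, known) shift for a substitution.

        A table entry for the reverse substitution is used with negated,
        swapped bounds.  Unknown substitutions get the zero-centred default
        interval and are logged as low-confidence.
        """
        key = (record.site, record.ref_residue, record.alt_residue)
        if key in self.shifts:
            lo, hi = self.shifts[key]
            return lo, hi, True
        rev = (record.site, record.alt_residue, record.ref_residue)
        if rev in self.shifts:
            lo, hi = self.shifts[rev]
            return -hi, -lo, True
        log.warning(
            "no tabulated shift for %s; using zero-centred +/-%g nm default",
            record.notation, self.default_halfwidth_nm,
        )
        w = self.default_halfwidth_nm
        return -w, w, False


@dataclass(frozen=True)
class TuningComparison:
    """Result of comparing two numbered sequences at the tuning sites."""

    substitutions: tuple[SubstitutionRecord, ...]
    uncallable_sites: tuple[int, ...]

    def __iter__(self):
        return iter(self.substitutions)

    def __len__(self) -> int:
        return len(self.substitutions)


def compare_tuning_sites(
    seq_a: NumberedSequence,
    seq_b: NumberedSequence,
    table: Optional[TuningSiteTable] = None,
) -> TuningComparison:
    """Call substitutions between two bovine-numbered sequences at tuning sites.

    Sites where either sequence has a gap (no residue mapped to that bovine
    position) are reported as uncallable rather than as substitutions.
    """
    if table is None:
        table = TuningSiteTable.default()
    records: list[SubstitutionRecord] = []
    uncallable: list[int] = []
    for site in table.sites:
        res_a = seq_a.residue_at(site)
        res_b = seq_b.residue_at(site)
        if res_a is None or res_b is None:
            uncallable.append(site)
        elif res_a != res_b:
            records.append(SubstitutionRecord(site, res_a, res_b))
    return TuningComparison(tuple(records), tuple(uncallable))


@dataclass(frozen=True)
class LambdaMaxEstimate:
    """Anchor-plus-shift lambda_max estimate with its uncertainty interval."""

    anchor_lambda_max_nm: float
    substitutions: tuple[SubstitutionRecord, ...]
    point_nm: float
    interval_nm: tuple[float, float]
    within_sws1_range: bool
    all_shifts_known: bool

    def summary(self) -> str:
        subs = ", ".join(s.notation for s in self.substitutions) or "none"
        lines = [
            "lambda_max estimate (anchor-plus-shift)",
            f"  anchor lambda_max : {self.anchor_lambda_max_nm:.1f} nm",
            f"  substitutions     : {subs}",
            f"  point estimate    : {self.point_nm:.1f} nm",
            f"  interval          : [{self.interval_nm[0]:.1f}, "
            f"{self.interval_nm[1]:.1f}] nm",
            f"  within SWS1 range ({SWS1_RANGE_NM[0]:.0f}-"
            f"{SWS1_RANGE_NM[1]:.0f} nm): {self.within_sws1_range}",
        ]
        if not self.all_shifts_known:
            lines.append("  note: one or more shifts used the default interval")
        return "\n".join(lines)


def estimate_lambda_max(
    anchor_nm: float,
    substitutions: Sequence[SubstitutionRecord],
    table: Optional[TuningSiteTable] = None,
) -> LambdaMaxEstimate:
    """Estimate lambda_max from an anchor homolog and tuning-site substitutions.

    The summed shift interval is added to the anchor.  The point estimate is
    the anchor itself when the summed interval contains zero — the data are
    then consistent with no net shift — and the interval midpoint otherwise.
    """
    lo_ok, hi_ok = _ANCHOR_RANGE
    if not (lo_ok <= anchor_nm <= hi_ok):
        raise ValueError(
            f"anchor lambda_max {anchor_nm} nm outside [{lo_ok}, {hi_ok}] nm"
        )
    if table is None:
        table = TuningSiteTable.default()

    shift_lo = 0.0
    shift_hi = 0.0
    all_known = True
    for record in substitutions:
        lo, hi, known = table.shift_interval(record)
        shift_lo += lo
        shift_hi += hi
        all_known = all_known and known

    interval = (anchor_nm + shift_lo, anchor_nm + shift_hi)
    if shift_lo <= 0.0 <= shift_hi:
        point = anchor_nm
    else:
        point = 0.5 * (interval[0] + interval[1])
    within = SWS1_RANGE_NM[0] <= point <= SWS1_RANGE_NM[1]
    return LambdaMaxEstimate(
        anchor_lambda_max_nm=float(anchor_nm),
        substitutions=tuple(substitutions),
        point_nm=float(point),
        interval_nm=interval,
        within_sws1_range=within,
        all_shifts_known=all_known,
    )


# -- FASTA I/O ---------------------------------------------------------------

def read_fasta(path: Union[str, Path]) -> list[tuple[str, str]]:
    """[(id, residues), ...] from an amino-acid FASTA file."""
    out = []
    for record in SeqIO.parse(str(path), "fasta"):
        out.append((record.id, _validate_protein(str(record.seq), record.id)))
    if not out:
        raise ValueError(f"{path}: no FASTA records")
    return out


def write_fasta(records: Sequence[tuple[str, str]], path: Union[str, Path]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for seq_id, residues in records:
            fh.write(f">{seq_id}\n")
            for i in range(0, len(residues), 60):
                fh.write(residues[i : i + 60] + "\n")
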