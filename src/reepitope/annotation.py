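"""Antibody V-region numbering, CDR definition and germline analysis.

Numbering is produced by alignment transfer: the query is globally aligned to
the best-matching reference germline whose FASTA header carries explicit
scheme numbers, and those numbers are transferred across aligned columns.
This is accurate for V regions at or near germline identity, which is the
regime focused re-engineering operates in (templates chosen for germline
likeness).  IMGT region boundaries: FR1 1–26, CDR1 27–38, FR2 39–55,
CDR2 56–65, FR3 66–104, CDR3 105–117, FR4 118–128.

Reference FASTA header dialect::

    >GENE_NAME|chain=H|imgt=1,2,3,...,104

``imgt=`` lists one scheme number per reference residue (IMGT germlines have
scheme gaps, so the list is explicit).  Without an ``imgt=`` field the
numbers default to 1..len(sequence).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "NumberedPosition",
    "AnnotatedAntibody",
    "GermlineAssignment",
    "GermlineReference",
    "read_germline_fasta",
    "region_of",
    "number_antibody",
    "assign_germline",
    "germline_flag_positions",
    "IMGT_CDR_BOUNDS",
]

IMGT_CDR_BOUNDS = {"CDR1": (27, 38), "CDR2": (56, 65), "CDR3": (105, 117)}
_IMGT_REGIONS = [
    ("FR1", 1, 26),
    ("CDR1", 27, 38),
    ("FR2", 39, 55),
    ("CDR2", 56, 65),
    ("FR3", 66, 104),
    ("CDR3", 105, 117),
    ("FR4", 118, 128),
]

_AA = set("ACDEFGHIKLMNPQRSTVWY")


def region_of(scheme_number: int, scheme: str = "imgt") -> str:
    """Region label (FR1..FR4 / CDR1..3) for an IMGT scheme number."""
    if scheme != "imgt":
        raise ValueError(f"unsupported scheme {scheme!r}")
    for name, lo, hi in _IMGT_REGIONS:
        if lo <= scheme_number <= hi:
            return name
    return "FR4" if scheme_number > 128 else "FR1"


@dataclasses.dataclass(frozen=True)
class NumberedPosition:
    scheme_number: int
    insertion_letter: str
    chain_type: str  # H, K or L
    region: str
    residue: str

    @property
    def key(self) -> tuple[str, int, str]:
        chain = "H" if self.chain_type == "H" else "L"
        return (chain, self.scheme_number, self.insertion_letter)


@dataclasses.dataclass(frozen=True)
class GermlineAssignment:
    gene_name: str
    percent_identity: float
    mutations: tuple[tuple[int, str, str], ...]  # (scheme number, germline res, observed res)
    compared_span: tuple[int, int]  # first/last scheme number compared


@dataclasses.dataclass
class AnnotatedAntibody:
    """Numbered heavy/light V regions with germline provenance per position.

    ``germline_flags`` maps position keys ('H'/'L', scheme number, insertion
    letter) to True (germline-identical), False (somatically mutated) or None
    (beyond germline V-gene coverage — CDR3 tail / FR4, never 'germline').
    """

    heavy: list[NumberedPosition]
    light: list[NumberedPosition]
    scheme: str = "imgt"
    germline_flags: dict[tuple[str, int, str], bool | None] = dataclasses.field(
        default_factory=dict
    )
    assigned_vgenes: dict[str, GermlineAssignment] = dataclasses.field(default_factory=dict)

    def positions(self, chain: str) -> list[NumberedPosition]:
        return self.heavy if chain == "H" else self.light

    def cdr_position_keys(self, chain: str) -> set[tuple[str, int, str]]:
        return {p.key for p in self.positions(chain) if p.region.startswith("CDR")}

    def flag_summary(self) -> dict[str, int]:
        vals = list(self.germline_flags.values())
        return {
            "germline": sum(v is True for v in vals),
            "mutated": sum(v is False for v in vals),
            "uncovered": sum(v is None for v in vals),
        }


@dataclasses.dataclass(frozen=True)
class GermlineReference:
    name: str
    chain_type: str  # H, K or L
    sequence: str
    numbers: tuple[int, ...]


def read_germline_fasta(source: str | Path | Iterable[str]) -> list[GermlineReference]:
    """Parse germline references from FASTA with the header dialect above."""
    if isinstance(source, (str, Path)):
        lines = Path(source).read_text().splitlines()
    else:
        lines = list(source)
    refs: list[GermlineReference] = []
    header: str | None = None
    seq_parts: list[str] = []

    def _flush():
        if header is None:
            return
        seq = "".join(seq_parts).upper()
        fields = header.split("|")
        name = fields[0].strip()
        chain_type = "H"
        numbers: tuple[int, ...] | None = None
        for f in fields[1:]:
            f = f.strip()
            if f.startswith("chain="):
                chain_type = f[len("chain="):].upper()
            elif f.startswith("imgt="):
                numbers = tuple(int(x) for x in f[len("imgt="):].split(","))
        if numbers is None:
            numbers = tuple(range(1, len(seq) + 1))
        if len(numbers) != len(seq):
            raise ValueError(
                f"reference {name}: {len(numbers)} scheme numbers for "
                f"{len(seq)} residues"
            )
        refs.append(GermlineReference(name, chain_type, seq, numbers))

    for line in lines:
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            _flush()
            header = line[1:]
            seq_parts = []
        else:
            seq_parts.append(line)
    _flush()
    return refs


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11.0
    al.extend_gap_score = -1.0
    al.mode = "global"
    # do not penalize terminal gaps: the query carries CDR3/J tail beyond V
    al.end_gap_score = 0.0
    return al


def _align(ref_seq: str, query_seq: str) -> list[tuple[int | None, int | None]]:
    """Aligned column list of (ref index, query index), None for gaps."""
    aln = _aligner().align(ref_seq, query_seq)[0]
    cols: list[tuple[int | None, int | None]] = []
    for (rs, re), (qs, qe) in zip(*aln.aligned):
        cols.append((rs, qs, re - rs))
    # expand blocks and interleave gap runs
    out: list[tuple[int | None, int | None]] = []
    prev_r, prev_q = 0, 0
    for rs, qs, length in cols:
        for r in range(prev_r, rs):
            out.append((r, None))
        for q in range(prev_q, qs):
            out.append((None, q))
        for k in range(length):
            out.append((rs + k, qs + k))
        prev_r, prev_q = rs + length, qs + length
    for r in range(prev_r, len(ref_seq)):
        out.append((r, None))
    for q in range(prev_q, len(query_seq)):
        out.append((None, q))
    return out


def _identity_to_ref(ref: GermlineReference, query: str) -> float:
    matches = sum(
        1
        for r, q in _align(ref.sequence, query)
        if r is not None and q is not None and ref.sequence[r] == query[q]
    )
    return 100.0 * matches / len(ref.sequence)


def _validate_seq(seq: str, label: str) -> str:
    seq = seq.strip().upper()
    if not seq or any(c not in _AA for c in seq):
        bad = sorted({c for c in seq if c not in _AA})
        raise ValueError(f"{label} sequence is not a plain amino-acid string: {bad}")
    return seq


def _best_reference(
    query: str, refs: Sequence[GermlineReference], chain_types: set[str]
) -> GermlineReference:
    candidates = [r for r in refs if r.chain_type in chain_types]
    if not candidates:
        raise ValueError(f"no germline references of chain type {sorted(chain_types)}")
    scored = sorted(
        candidates, key=lambda r: (-_identity_to_ref(r, query), r.name)
    )
    best = scored[0]
    if _identity_to_ref(best, query) < 50.0:
        raise ValueError(
            f"best reference {best.name} is below 50% identity — "
            "query may be the wrong chain type"
        )
    return best


def _number_chain(
    query: str, ref: GermlineReference
) -> tuple[list[NumberedPosition], set[int]]:
    """Number one chain against one reference; returns positions and the set
    of scheme numbers covered by the reference alignment."""
    cols = _align(ref.sequence, query)
    # require the alignment to reach the end of FR3 on the reference
    max_ref_num = max(
        (ref.numbers[r] for r, q in cols if r is not None and q is not None),
        default=0,
    )
    if max_ref_num < 104:
        raise ValueError(
            "query V region too short: alignment covers scheme numbers only "
            f"up to {max_ref_num} (< 104, end of FR3)"
        )
    positions: list[NumberedPosition] = []
    covered: set[int] = set()
    last_num = 0
    insertion_run = 0
    tail_mode = False
    pending_q: list[int] = []

    chain_type = ref.chain_type

    def _emit(num: int, ins: str, qi: int):
        positions.append(
            NumberedPosition(
                scheme_number=num,
                insertion_letter=ins,
                chain_type=chain_type,
                region=region_of(num),
                residue=query[qi],
            )
        )

    matched_cols = [(r, q) for r, q in cols]
    for r, q in matched_cols:
        if r is not None and q is not None:
            # flush any queued query insertions as insertion-lettered positions
            for k, qi in enumerate(pending_q):
                _emit(last_num, chr(ord("A") + k), qi)
            pending_q = []
            num = ref.numbers[r]
            _emit(num, "", q)
            covered.add(num)
            last_num = num
        elif r is None and q is not None:
            pending_q.append(q)
        # ref residue deleted in query: nothing to emit
    # residues beyond the reference (CDR3 tail / FR4): sequential numbers
    for qi in pending_q:
        last_num += 1
        _emit(last_num, "", qi)
    return positions, covered


def number_antibody(
    heavy_seq: str,
    light_seq: str,
    scheme: str = "imgt",
    reference_set: str | Path | Sequence[GermlineReference] = (),
) -> AnnotatedAntibody:
    """Number a paired Fv under IMGT by alignment transfer from references.

    Every input residue appears exactly once in the output; residues beyond
    the reference V gene continue with sequential numbers (CDR3 tail, FR4).
    """
    if scheme != "imgt":
        raise ValueError(f"unsupported scheme {scheme!r}")
    refs = (
        read_germline_fasta(reference_set)
        if isinstance(reference_set, (str, Path))
        else list(reference_set)
    )
    heavy_seq = _validate_seq(heavy_seq, "heavy")
    light_seq = _validate_seq(light_seq, "light")
    ref_h = _best_reference(heavy_seq, refs, {"H"})
    ref_l = _best_reference(light_seq, refs, {"K", "L"})
    heavy, _ = _number_chain(heavy_seq, ref_h)
    light, _ = _number_chain(light_seq, ref_l)
    return AnnotatedAntibody(heavy=heavy, light=light, scheme=scheme)


def assign_germline(
    v_seq: str, germline_set: str | Path | Sequence[GermlineReference],
    chain_types: set[str] | None = None,
) -> GermlineAssignment:
    """Assign the highest-identity germline V gene to a query V region.

    Identity is computed over the germline span only (query CDR3/J tail is
    excluded); gaps count as mismatches; ties break to the alphabetically
    first gene name.
    """
    refs = (
        read_germline_fasta(germline_set)
        if isinstance(germline_set, (str, Path))
        else list(germline_set)
    )
    if chain_types:
        refs = [r for r in refs if r.chain_type in chain_types]
    if not refs:
        raise ValueError("empty germline reference set")
    v_seq = _validate_seq(v_seq, "query")
    best: tuple[float, str, GermlineReference] | None = None
    for ref in refs:
        ident = _identity_to_ref(ref, v_seq)
        key = (-ident, ref.name)
        if best is None or key < (-best[0], best[1]):
            best = (ident, ref.name, ref)
    ident, _, ref = best
    mutations: list[tuple[int, str, str]] = []
    for r, q in _align(ref.sequence, v_seq):
        if r is None:
            continue
        germ_res = ref.sequence[r]
        obs = v_seq[q] if q is not None else "-"
        if obs != germ_res:
            mutations.append((ref.numbers[r], germ_res, obs))
    return GermlineAssignment(
        gene_name=ref.name,
        percent_identity=round(ident, 6),
        mutations=tuple(mutations),
        compared_span=(ref.numbers[0], ref.numbers[-1]),
    )


def germline_flag_positions(
    annotated: AnnotatedAntibody,
    assignments: Mapping[str, GermlineAssignment],
    coverage: Mapping[str, set[int]] | None = None,
) -> AnnotatedAntibody:
    """Set per-position germline flags from per-chain germline assignments.

    ``assignments`` maps 'H'/'L' to the chain's GermlineAssignment.  Positions
    whose scheme number lies within the assignment's compared span are flagged
    True (germline) or False (listed as a mutation); positions beyond the span
    are flagged None (uncovered).
    """
    flags: dict[tuple[str, int, str], bool | None] = {}
    for chain in ("H", "L"):
        if chain not in assignments:
            continue
        asn = assignments[chain]
        mutated_numbers = {m[0] for m in asn.mutations}
        lo, hi = asn.compared_span
        for pos in annotated.positions(chain):
            key = pos.key
            if pos.insertion_letter or not (lo <= pos.scheme_number <= hi):
                flags[key] = None
            elif coverage is not None and pos.scheme_number not in coverage.get(chain, set()):
                flags[key] = None
            else:
                flags[key] = pos.scheme_number not in mutated_numbers
    annotated.germline_flags = flags
    annotated.assigned_vgenes = dict(assignments)
    return annotated
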