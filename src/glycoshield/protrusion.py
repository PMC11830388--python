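"""Extracellular-domain protrusion from Cα coordinates and membrane topology.

The protrusion statistic is the maximal Euclidean distance (Å) between the
Cα of the membrane-adjacent anchor residue of an extracellular segment and
the Cα of any residue in that segment; for multi-pass proteins the reported
value is the maximum over extracellular segments.  It is a proxy for how far
a surface protein extends above the glycocalyx, and hence for whether its
epitopes escape glycosphingolipid shielding.

Transmembrane spans are consumed as explicit configuration (for example
transcribed from UniProt annotation) rather than predicted.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CaTrace",
    "TopologyAnnotation",
    "Segment",
    "SegmentProtrusion",
    "ProtrusionResult",
    "GroupComparison",
    "load_ca_trace",
    "ecd_segments",
    "max_protrusion",
    "protrusion_result",
    "compare_groups",
    "load_table1",
]


@dataclass
class CaTrace:
    """Ordered Cα records of one chain: residue numbers, names, coordinates."""

    chain: str
    residue_numbers: np.ndarray  # (n,) int
    residue_names: list[str]
    coordinates: np.ndarray  # (n, 3) float, Å

    def __post_init__(self) -> None:
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if len(self.residue_numbers) != len(self.coordinates):
            raise ValueError("residue numbers and coordinates length mismatch")
        if len(np.unique(self.residue_numbers)) != len(self.residue_numbers):
            raise ValueError("duplicate residue numbers in trace")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates in trace")

    def __len__(self) -> int:
        return len(self.residue_numbers)

    def coordinate_of(self, resnum: int) -> np.ndarray:
        idx = np.flatnonzero(self.residue_numbers == resnum)
        if len(idx) == 0:
            raise KeyError(resnum)
        return self.coordinates[idx[0]]


def load_ca_trace(path, chain: str | None = None) -> CaTrace:
    """Extract the Cα trace of one chain from a PDB or mmCIF file.

    Model 1 only; alternate locations are resolved to the highest-occupancy
    conformer (ties to the first).  With ``chain=None`` a single-chain file is
    accepted; otherwise the available chain ids are listed in the error.
    """
    import gemmi

    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    model = structure[0]
    names = [ch.name for ch in model]
    if chain is None:
        if len(names) != 1:
            raise ValueError(f"multiple chains {names}; specify one")
        chain = names[0]
    if chain not in names:
        raise ValueError(f"chain {chain!r} not found; available: {names}")

    resnums, resnames, coords = [], [], []
    for res in model[chain]:
        best = None
        for atom in res:
            if atom.name != "CA":
                continue
            if best is None or atom.occ > best.occ:
                best = atom
        if best is None:
            continue
        resnums.append(res.seqid.num)
        resnames.append(res.name)
        coords.append([best.pos.x, best.pos.y, best.pos.z])
    if not coords:
        raise ValueError(f"no CA atoms found in chain {chain!r} of {path}")
    return CaTrace(chain, np.array(resnums), resnames, np.array(coords))


@dataclass(frozen=True)
class TopologyAnnotation:
    """Membrane topology of one chain.

    ``tm_spans`` are inclusive residue-number intervals, sorted and
    non-overlapping; ``n_term`` gives the side of the N-terminus (``out`` =
    extracellular).  An optional conformation tag (e.g. ``inactive`` for
    integrins) is carried for provenance.
    """

    chain: str
    tm_spans: tuple[tuple[int, int], ...] = ()
    n_term: str = "out"
    conformation: str | None = None

    def __post_init__(self) -> None:
        if self.n_term not in ("in", "out"):
            raise ValueError("n_term must be 'in' or 'out'")
        spans = tuple((int(a), int(b)) for a, b in self.tm_spans)
        for a, b in spans:
            if a > b:
                raise ValueError(f"invalid TM span ({a}, {b})")
        for (_, b1), (a2, _) in zip(spans, spans[1:]):
            if a2 <= b1:
                raise ValueError("TM spans must be sorted and non-overlapping")
        object.__setattr__(self, "tm_spans", spans)


@dataclass(frozen=True)
class Segment:
    """An extracellular residue range with its membrane-adjacent anchor."""

    start: int
    end: int  # inclusive
    anchor: int


def ecd_segments(trace: CaTrace, topology: TopologyAnnotation) -> list[Segment]:
    """Derive extracellular segments by alternating sidedness across TM spans.

    The side of each inter-TM segment alternates starting from the N-terminus
    orientation.  The anchor is the segment residue adjacent to a TM span: for
    an extracellular N-terminal segment, its last residue (immediately before
    the first TM); for loops and the C-terminal segment, the first residue
    after the preceding TM.  With no TM spans the whole chain is one segment
    anchored at its first residue (with a warning).
    """
    first, last = int(trace.residue_numbers.min()), int(trace.residue_numbers.max())
    if not topology.tm_spans:
        warnings.warn("no TM spans given; treating entire chain as one segment")
        return [Segment(first, last, first)]
    for a, b in topology.tm_spans:
        if a < first or b > last:
            raise ValueError(
                f"TM span ({a}, {b}) outside trace residue range [{first}, {last}]"
            )

    segments: list[Segment] = []
    side = topology.n_term
    prev_end = None  # end of preceding TM span
    boundaries = list(topology.tm_spans) + [None]
    for span in boundaries:
        seg_start = first if prev_end is None else prev_end + 1
        seg_end = last if span is None else span[0] - 1
        if seg_start <= seg_end and side == "out":
            anchor = seg_end if prev_end is None else seg_start
            segments.append(Segment(seg_start, seg_end, anchor))
        side = "in" if side == "out" else "out"
        if span is not None:
            prev_end = span[1]
    return segments


@dataclass(frozen=True)
class SegmentProtrusion:
    segment: Segment
    distance: float  # Å
    argmax_residue: int
    n_missing: int  # segment residues without a Cα


def max_protrusion(
    trace: CaTrace, segment: Segment, metric: str = "anchor"
) -> SegmentProtrusion:
    """Maximal Cα distance within one extracellular segment.

    ``metric='anchor'`` (default) measures from the anchor residue to every
    segment residue; ``metric='diameter'`` takes the all-pairs maximum.
    Segment residues missing a Cα are skipped and counted.
    """
    mask = (trace.residue_numbers >= segment.start) & (
        trace.residue_numbers <= segment.end
    )
    coords = trace.coordinates[mask]
    resnums = trace.residue_numbers[mask]
    if len(coords) == 0:
        raise ValueError(f"segment {segment} has no resolved residues")
    n_missing = (segment.end - segment.start + 1) - len(coords)
    if metric == "anchor":
        anchor_xyz = trace.coordinate_of(segment.anchor)
        d = np.linalg.norm(coords - anchor_xyz, axis=1)
        i = int(np.argmax(d))
        return SegmentProtrusion(segment, float(d[i]), int(resnums[i]), n_missing)
    if metric == "diameter":
        diff = coords[:, None, :] - coords[None, :, :]
        d = np.linalg.norm(diff, axis=-1)
        i, j = np.unravel_index(np.argmax(d), d.shape)
        return SegmentProtrusion(segment, float(d[i, j]), int(resnums[j]), n_missing)
    raise ValueError(f"unknown metric {metric!r}")


@dataclass(frozen=True)
class ProtrusionResult:
    """Per-segment protrusions and the reported (maximal) value for a protein."""

    protein: str
    segments: tuple[SegmentProtrusion, ...]

    @property
    def protrusion(self) -> float:
        return max(s.distance for s in self.segments)

    @property
    def reported(self) -> float:
        # 0.1 Å reporting precision
        return round(self.protrusion, 1)


def protrusion_result(
    protein: str,
    trace: CaTrace,
    topology: TopologyAnnotation,
    metric: str = "anchor",
) -> ProtrusionResult:
    """Compute per-segment and overall protrusion for one protein."""
    segs = ecd_segments(trace, topology)
    if not segs:
        raise ValueError(f"{protein}: no extracellular segments under this topology")
    return ProtrusionResult(
        protein, tuple(max_protrusion(trace, s, metric) for s in segs)
    )


@dataclass(frozen=True)
class GroupComparison:
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t: float
    p: float
    equal_var: bool


def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float], equal_var: bool = True
) -> GroupComparison:
    """Two-sample Student's t comparison of protrusion groups.

    Arithmetic means, sample (n-1) standard deviations and the two-sided
    pooled-variance t test (Welch via ``equal_var=False``).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(
        float(a.mean()), float(a.std(ddof=1)), len(a),
        float(b.mean()), float(b.std(ddof=1)), len(b),
        float(t), float(p), equal_var,
    )


def load_table1() -> pd.DataFrame:
    """Packaged extracellular-domain sizes (Å) with affected/non-affected labels.

    Fifteen proteins: seven whose tested epitopes were all shielded, eight
    with at least one unshielded epitope.
    """
    ref = importlib.resources.files("glycoshield.data") / "table1_ecd_sizes.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")
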