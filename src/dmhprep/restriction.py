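"""Restriction-fragment logic of the DMH protocol.

The DMH protocol digests linker-ligated DNA with two methylation-sensitive
restriction enzymes, HpaII and HinP1I, whose recognition sites (as used
throughout this package) are CCGG and CGCG.  A fragment survives digestion
— and therefore contributes signal on the array — only if every recognition
site it carries is methylated (vacuously, if it carries none).

A probe whose surrounding L-base window (L = 900 by default, matching
~400-500 bp sonication fragments landing on either side of the probe
center) contains *no* recognition site receives identical material from
both channels regardless of methylation state: it is an internal control
probe with theoretical log-ratio M = 0.  Both default motifs are their own
reverse complements, so a single-strand scan suffices; users configuring
other enzymes must supply both strands' motifs themselves.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

from .exceptions import InputError
from .io import GenomeSequences, ProbeAnnotation

#: Recognition sites of HpaII and HinP1I as used by the DMH protocol.
DEFAULT_MOTIFS: tuple[str, ...] = ("CCGG", "CGCG")

#: Default window length (bases) around a probe center that must be free
#: of recognition sites for the probe to qualify as an internal control.
DEFAULT_WINDOW = 900

RETAINED = "RETAINED"
DIGESTED = "DIGESTED"

_VALID = frozenset("ACGTN")


@dataclasses.dataclass(frozen=True)
class RecognitionSite:
    """One recognition-motif occurrence within a sequence.

    ``offset`` is the 0-based position of the motif start; ``methylated``
    is carried for simulation and worked-example use.
    """

    offset: int
    motif: str
    methylated: bool = False


@dataclasses.dataclass
class ControlProbeSet:
    """Probe ids whose theoretical log-ratio is zero under DMH."""

    probe_ids: frozenset
    window_length: int = DEFAULT_WINDOW

    def __contains__(self, probe_id) -> bool:
        return probe_id in self.probe_ids

    def __len__(self) -> int:
        return len(self.probe_ids)


def _check_sequence(seq: str) -> None:
    if not _VALID.issuperset(seq):
        bad = sorted(set(seq) - _VALID)
        raise InputError(f"sequence contains invalid characters {bad}; expected uppercase A/C/G/T/N")


def find_recognition_sites(
    seq: str, motifs: Sequence[str] = DEFAULT_MOTIFS
) -> list[RecognitionSite]:
    """All occurrences of the recognition motifs in ``seq``, sorted by offset.

    Overlapping occurrences are all reported (any unmethylated occurrence
    can be cut).  N never matches.  Lowercase or non-nucleotide characters
    raise :class:`InputError`.
    """
    _check_sequence(seq)
    sites = []
    for motif in motifs:
        start = 0
        while True:
            hit = seq.find(motif, start)
            if hit < 0:
                break
            sites.append(RecognitionSite(offset=hit, motif=motif))
            start = hit + 1  # step one base: keep overlapping occurrences
    sites.sort(key=lambda s: (s.offset, s.motif))
    return sites


def classify_fragment(
    seq: str,
    methylated_offsets: Iterable[int] = (),
    motifs: Sequence[str] = DEFAULT_MOTIFS,
) -> str:
    """Digestion fate of a fragment given which site offsets are methylated.

    Returns ``"RETAINED"`` iff every recognition site in ``seq`` is
    methylated (vacuously true for site-free fragments), ``"DIGESTED"``
    otherwise.  An offset that is not a real site raises
    :class:`InputError`.
    """
    sites = find_recognition_sites(seq, motifs)
    offsets = {s.offset for s in sites}
    methylated = set(methylated_offsets)
    if not methylated.issubset(offsets):
        bogus = sorted(methylated - offsets)
        raise InputError(f"methylated offsets {bogus} are not recognition sites")
    return RETAINED if offsets.issubset(methylated) else DIGESTED


def count_sites_in_window(
    seq: str, center: int, window: int, motifs: Sequence[str] = DEFAULT_MOTIFS
) -> int:
    """Number of complete motif occurrences inside ``[center - window/2,
    center + window/2)``, truncated at the sequence ends.

    A motif counts only if all of its bases lie inside the window.
    """
    half = window // 2
    lo = max(0, center - half)
    hi = min(len(seq), center + half)
    if hi <= lo:
        return 0
    return len(find_recognition_sites(seq[lo:hi], motifs))


def identify_control_probes(
    annotation: ProbeAnnotation,
    genome: GenomeSequences,
    window: int = DEFAULT_WINDOW,
    motifs: Sequence[str] = DEFAULT_MOTIFS,
) -> ControlProbeSet:
    """Identify internal control probes: recognition-site-free windows.

    A probe is a control iff the ``window``-base region centered on
    floor((start + end) / 2) contains zero complete recognition-motif
    occurrences.  Windows truncated at chromosome ends are scanned over
    their available extent.  Unknown chromosomes raise
    :class:`InputError` naming the probe.
    """
    if window <= 0 or window % 2 != 0:
        raise InputError(f"window length must be positive and even, got {window}")
    controls = set()
    d = annotation.data
    for probe_id, chrom, start, end in zip(d["probe_id"], d["chrom"], d["start"], d["end"]):
        if chrom not in genome:
            raise InputError(f"probe {probe_id!r}: chromosome {chrom!r} not in genome")
        center = (start + end) // 2
        if count_sites_in_window(genome[chrom], center, window, motifs) == 0:
            controls.add(probe_id)
    return ControlProbeSet(probe_ids=frozenset(controls), window_length=window)
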