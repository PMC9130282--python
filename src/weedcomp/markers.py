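"""Target-site-resistance screen: in-silico PCR, codon-aware substitution
calls, and flagging of known ALS / ACCase resistance positions.

Herbicide target-site resistance in blackgrass arises from amino-acid
substitutions in acetolactate synthase (ALS, e.g. Pro197 changes) and
acetyl-CoA carboxylase (ACCase, e.g. Trp1999Leu).  The screen locates the
PCR product a primer pair would amplify from a template, compares the
in-frame region codon by codon against a reference CDS, classifies each
change as synonymous or nonsynonymous, and flags nonsynonymous calls at
positions known to confer resistance.

Coordinates are 0-based half-open internally and 1-based in reports.
Primer matching is exact by default (Sanger-amplicon context); a mismatch
tolerance is opt-in.  Indels are out of scope: unequal CDS lengths are an
error, not an alignment trigger.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from Bio.Data import CodonTable
from Bio.Seq import Seq

from . import fixtures

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


class NoAmpliconError(ValueError):
    """The primer pair has no binding-site pair on the template."""


class FrameError(ValueError):
    """Reference and query CDS are incompatible (length or frame)."""


@dataclass
class Amplicon:
    template_id: str
    start: int      # 0-based inclusive
    end: int        # 0-based exclusive
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SubstitutionCall:
    codon_index_local: int      # 1-based codon index in the analysed region
    position_standard: int      # standard amino-acid numbering
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    kind: str                   # "synonymous" | "nonsynonymous"
    indeterminate: bool = False


@dataclass
class ResistanceCall:
    gene: str
    label: str                  # e.g. "P197A", "W1999L"
    known_resistance: bool
    note: str = ""


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC-aware via biopython)."""
    return str(Seq(seq).reverse_complement())


def translate_codon(codon: str) -> str:
    """Single-letter amino acid (or '*') for an ACGT codon; 'X' if ambiguous."""
    c = codon.upper()
    if len(c) != 3:
        raise ValueError(f"codon must have length 3, got {codon!r}")
    if set(c) - set("ACGT"):
        return "X"
    if c in _STANDARD_TABLE.stop_codons:
        return "*"
    return _STANDARD_TABLE.forward_table[c]


def _sites(template: str, probe: str, max_mismatches: int) -> list[int]:
    """Start positions where probe matches template with <= max_mismatches."""
    hits = []
    if max_mismatches == 0:
        start = template.find(probe)
        while start != -1:
            hits.append(start)
            start = template.find(probe, start + 1)
        return hits
    n, m = len(template), len(probe)
    for i in range(n - m + 1):
        window = template[i : i + m]
        mism = sum(1 for a, b in zip(window, probe) if a != b)
        if mism <= max_mismatches:
            hits.append(i)
    return hits


def find_amplicon(
    template: str,
    primer_fwd: str,
    primer_rev: str,
    max_mismatches: int = 0,
    template_id: str = "",
) -> Amplicon:
    """Locate the PCR product a primer pair defines on the plus strand.

    The forward primer binds the plus strand; the reverse primer binds the
    minus strand, so its reverse complement is searched downstream on the
    plus strand.  The product spans both primer sites inclusive.  On
    ambiguity the leftmost-shortest product is returned and a warning lists
    all candidate products.
    """
    for name, p in (("forward", primer_fwd), ("reverse", primer_rev)):
        if len(p) < 15:
            raise ValueError(f"{name} primer shorter than 15 nt")
    template = template.upper()
    if set(template) - set("ACGTN"):
        raise ValueError("template alphabet must be ACGTN")
    fwd = primer_fwd.upper()
    rev_site = revcomp(primer_rev.upper())

    fwd_hits = _sites(template, fwd, max_mismatches)
    rev_hits = _sites(template, rev_site, max_mismatches)
    products = [
        (f, r + len(rev_site))
        for f in fwd_hits
        for r in rev_hits
        if r >= f + len(fwd)
    ]
    if not products:
        raise NoAmpliconError("no forward/reverse binding-site pair on the template")
    products.sort(key=lambda se: (se[0], se[1]))
    if len(products) > 1:
        listing = ", ".join(f"[{s}, {e}) ({e - s} bp)" for s, e in products)
        warnings.warn(f"multiple candidate products: {listing}; "
                      "returning the leftmost-shortest", stacklevel=2)
    start, end = products[0]
    return Amplicon(template_id=template_id, start=start, end=end,
                    sequence=template[start:end])


def call_substitutions(
    ref_cds: str, query_cds: str, numbering_offset: int = 0
) -> list[SubstitutionCall]:
    """Codon-by-codon comparison of two equal-length in-frame sequences.

    One call per changed codon; ``position_standard = codon_index_local +
    numbering_offset`` maps the local (1-based) codon index into the
    standard numbering of the full protein.  A changed codon containing an
    ambiguous base yields a call marked indeterminate.
    """
    ref = ref_cds.upper()
    qry = query_cds.upper()
    if len(ref) != len(qry):
        raise FrameError(f"length mismatch: {len(ref)} vs {len(qry)}")
    if len(ref) % 3 != 0:
        raise FrameError(f"length {len(ref)} is not divisible by 3")
    calls = []
    for i in range(0, len(ref), 3):
        rc, qc = ref[i : i + 3], qry[i : i + 3]
        if rc == qc:
            continue
        local = i // 3 + 1
        ambiguous = bool(set(rc + qc) - set("ACGT"))
        ref_aa = translate_codon(rc)
        alt_aa = translate_codon(qc)
        kind = "synonymous" if ref_aa == alt_aa else "nonsynonymous"
        calls.append(
            SubstitutionCall(
                codon_index_local=local,
                position_standard=local + numbering_offset,
                ref_codon=rc,
                alt_codon=qc,
                ref_aa=ref_aa,
                alt_aa=alt_aa,
                kind=kind,
                indeterminate=ambiguous,
            )
        )
    return calls


def flag_resistance(
    calls: list[SubstitutionCall],
    gene: str,
    known_table: dict[str, dict[int, list[str]]] | None = None,
) -> list[ResistanceCall]:
    """Label nonsynonymous calls and flag those at known resistance positions.

    The default table ships with ALS Pro197 (including P197A and P197T) and
    ACCase Trp1999 (including W1999L); any nonsynonymous change at a listed
    position is flagged, with the note recording whether the specific
    replacement residue is itself documented.
    """
    table = known_table if known_table is not None else fixtures.known_resistance_table()
    known = table.get(gene, {})
    out = []
    for call in calls:
        if call.kind != "nonsynonymous" or call.indeterminate:
            continue
        label = f"{call.ref_aa}{call.position_standard}{call.alt_aa}"
        if call.position_standard in known:
            documented = call.alt_aa in known[call.position_standard]
            note = ("documented resistance substitution" if documented
                    else "novel substitution at a known resistance position")
            out.append(ResistanceCall(gene=gene, label=label,
                                      known_resistance=True, note=note))
        else:
            out.append(ResistanceCall(gene=gene, label=label,
                                      known_resistance=False,
                                      note="position not in the known-resistance table"))
    return out


def screen_summary(calls: list[SubstitutionCall],
                   flagged: list[ResistanceCall] | None = None) -> dict:
    """Counts of synonymous / nonsynonymous calls plus flagged labels.

    Duplicate calls at one codon are collapsed (first occurrence wins) and
    indeterminate calls are excluded from the counts.
    """
    seen: dict[int, SubstitutionCall] = {}
    for call in calls:
        seen.setdefault(call.codon_index_local, call)
    determinate = [c for c in seen.values() if not c.indeterminate]
    n_syn = sum(1 for c in determinate if c.kind == "synonymous")
    n_non = sum(1 for c in determinate if c.kind == "nonsynonymous")
    labels = [r.label for r in flagged or [] if r.known_resistance]
    return {
        "n_synonymous": n_syn,
        "n_nonsynonymous": n_non,
        "n_indeterminate": sum(1 for c in seen.values() if c.indeterminate),
        "flagged": labels,
    }


def screen_template(
    gene: str,
    template: str,
    reference_cds: str,
    numbering_offset: int,
    primer_fwd: str,
    primer_rev: str,
    cds_start_in_amplicon: int = 0,
    max_mismatches: int = 0,
    known_table: dict | None = None,
    template_id: str = "",
) -> dict:
    """Full screen of one template: amplicon -> calls -> flags -> summary.

    ``cds_start_in_amplicon`` gives the 0-based offset of the in-frame
    region within the amplicon; the analysed region has the length of the
    reference CDS.
    """
    amp = find_amplicon(template, primer_fwd, primer_rev,
                        max_mismatches=max_mismatches, template_id=template_id)
    region = amp.sequence[cds_start_in_amplicon : cds_start_in_amplicon + len(reference_cds)]
    if len(region) != len(reference_cds):
        raise FrameError("amplicon too short for the configured in-frame region")
    calls = call_substitutions(reference_cds, region, numbering_offset)
    flagged = flag_resistance(calls, gene, known_table)
    summary = screen_summary(calls, flagged)
    return {"amplicon": amp, "calls": calls, "resistance": flagged,
            "summary": summary}
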