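"""Rule filter defining CutF-like candidate proteins inside anchor windows.

A candidate is a window gene whose protein (i) is smaller than 170
residues, (ii) matches no known Pfam-style domain, (iii) carries a
predicted Sec signal peptide, (iv) contains a CXXXC-type cysteine motif in
the central region, and (v) ends with a PP motif near the C-terminus.

The signal-peptide call is a deterministic tripartite heuristic
(positively charged n-region, hydrophobic h-region, A-X-A cleavage site);
externally computed calls can be supplied as a TSV and take precedence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genome_model import Gene, DomainHit

# Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}

SMALL_CLEAVAGE_RESIDUES = frozenset("AGST")

DEFAULT_MOTIF_PATTERNS = ("CXXXC", "CXXC")


@dataclass(frozen=True)
class MotifSpec:
    """Cysteine-motif patterns (X = any residue) and a positional window.

    ``region`` restricts matches to a fractional interval of the protein
    (default central 20-80%); None disables the restriction.
    """

    patterns: tuple[str, ...] = DEFAULT_MOTIF_PATTERNS
    region: tuple[float, float] | None = (0.20, 0.80)

    def __post_init__(self) -> None:
        for p in self.patterns:
            if sum(1 for c in p if c != "X") < 2:
                raise ValueError(f"pattern {p!r} needs >=2 literal residues")


@dataclass(frozen=True)
class SignalCall:
    """Outcome of signal-peptide prediction for one protein."""

    has_sp: bool
    cleavage_pos: int | None  # 1-based index of the last signal residue
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.has_sp and not (15 <= (self.cleavage_pos or 0) <= 40):
            raise ValueError("cleavage_pos must lie in [15, 40] when has_sp")


@dataclass(frozen=True)
class FilterDecision:
    """Per-rule flags for one gene; passed == conjunction of all flags."""

    gene_id: str
    size_ok: bool
    no_known_domain: bool
    signal_ok: bool
    internal_motif_ok: bool
    cterm_pp_ok: bool

    @property
    def passed(self) -> bool:
        return (
            self.size_ok
            and self.no_known_domain
            and self.signal_ok
            and self.internal_motif_ok
            and self.cterm_pp_ok
        )


def scan_motif(protein: str, spec: MotifSpec) -> list[tuple[str, int]]:
    """All (pattern, 1-based start) matches; overlaps allowed.

    Pattern X matches any residue; an X in the protein never matches a
    literal pattern residue.  The positional region restriction is NOT
    applied here (see apply_rules) — every match is returned.
    """
    out: list[tuple[str, int]] = []
    for pattern in spec.patterns:
        plen = len(pattern)
        for i in range(len(protein) - plen + 1):
            ok = True
            for pc, sc in zip(pattern, protein[i : i + plen]):
                if pc != "X" and sc != pc:
                    ok = False
                    break
            if ok:
                out.append((pattern, i + 1))
    out.sort(key=lambda m: (m[1], m[0]))
    return out


def has_cterm_pp(protein: str, tail_len: int = 15) -> bool:
    """True iff "PP" occurs within the last ``tail_len`` residues."""
    if tail_len < 2:
        raise ValueError("tail_len must be >= 2")
    return "PP" in protein[-tail_len:]


def predict_signal_peptide(
    protein: str,
    min_cleavage: int = 15,
    max_cleavage: int = 40,
    h_window: int = 8,
    min_hydropathy: float = 1.6,
) -> SignalCall:
    """Heuristic Sec signal-peptide call.

    A cleavage position c (1-based, last residue of the signal) is valid if
    all three classic signal regions are present:

    * n-region: at least one K/R among residues 2-5;
    * h-region: some ``h_window``-residue window fully inside residues
      6..c-4 with mean Kyte-Doolittle hydropathy >= ``min_hydropathy``;
    * c-region: residues c-2 and c are small (A/G/S/T), the A-X-A rule,
      with cleavage after c.

    The call uses the smallest valid c; the score is the best window
    hydropathy.  Proteins shorter than 25 residues are never called.
    """
    if len(protein) < 25:
        return SignalCall(has_sp=False, cleavage_pos=None, score=0.0)
    n_region_ok = any(res in "KR" for res in protein[1:5])
    if not n_region_ok:
        return SignalCall(has_sp=False, cleavage_pos=None, score=0.0)
    hydro = [KYTE_DOOLITTLE.get(res, 0.0) for res in protein]
    best_score = 0.0
    for c in range(min_cleavage, min(max_cleavage, len(protein)) + 1):
        if protein[c - 1] not in SMALL_CLEAVAGE_RESIDUES:
            continue
        if protein[c - 3] not in SMALL_CLEAVAGE_RESIDUES:
            continue
        # h-region windows fully within residues 6..c-4 (1-based).
        lo, hi = 6, c - 4
        found = False
        for w0 in range(lo, hi - h_window + 2):
            mean_h = sum(hydro[w0 - 1 : w0 - 1 + h_window]) / h_window
            if mean_h >= min_hydropathy:
                found = True
                best_score = max(best_score, mean_h)
        if found:
            return SignalCall(has_sp=True, cleavage_pos=c, score=best_score)
    return SignalCall(has_sp=False, cleavage_pos=None, score=0.0)


def read_signal_table(path) -> dict[str, SignalCall]:
    """Read external signal-peptide calls (gene_id, has_sp, cleavage_pos)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    calls: dict[str, SignalCall] = {}
    for rec in df.itertuples(index=False):
        has_sp = str(rec.has_sp).strip().lower() in ("1", "true", "yes")
        pos = int(rec.cleavage_pos) if has_sp else None
        score = float(getattr(rec, "score", 0.0) or 0.0)
        calls[rec.gene_id] = SignalCall(has_sp=has_sp, cleavage_pos=pos, score=score)
    return calls


def _motif_in_region(protein: str, spec: MotifSpec) -> bool:
    matches = scan_motif(protein, spec)
    if spec.region is None:
        return bool(matches)
    lo_frac, hi_frac = spec.region
    n = len(protein)
    for pattern, start in matches:
        center = start - 1 + len(pattern) / 2.0
        if lo_frac * n <= center <= hi_frac * n:
            return True
    return False


def apply_rules(
    gene: Gene,
    domain_hits: list[DomainHit],
    signal_calls: dict[str, SignalCall] | None = None,
    spec: MotifSpec = MotifSpec(),
    max_len: int = 170,
    domain_evalue_max: float = 1e-5,
) -> FilterDecision:
    """Evaluate the five candidate rules for one gene.

    ``signal_calls`` (external table) takes precedence over the built-in
    heuristic.  The size rule is strict: length must be < max_len.
    """
    size_ok = gene.length_aa < max_len
    no_known_domain = not any(
        h.gene_id == gene.gene_id and h.evalue <= domain_evalue_max
        for h in domain_hits
    )
    if signal_calls is not None and gene.gene_id in signal_calls:
        signal_ok = signal_calls[gene.gene_id].has_sp
    else:
        signal_ok = predict_signal_peptide(gene.protein).has_sp
    internal_motif_ok = _motif_in_region(gene.protein, spec)
    cterm_pp_ok = has_cterm_pp(gene.protein)
    decision = FilterDecision(
        gene_id=gene.gene_id,
        size_ok=size_ok,
        no_known_domain=no_known_domain,
        signal_ok=signal_ok,
        internal_motif_ok=internal_motif_ok,
        cterm_pp_ok=cterm_pp_ok,
    )
    # Postcondition: passed is exactly the conjunction of the five flags.
    assert decision.passed == (
        size_ok and no_known_domain and signal_ok
        and internal_motif_ok and cterm_pp_ok
    )
    return decision


def decisions_to_frame(decisions: list[FilterDecision]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": d.gene_id,
                "size_ok": d.size_ok,
                "no_known_domain": d.no_known_domain,
                "signal_ok": d.signal_ok,
                "internal_motif_ok": d.internal_motif_ok,
                "cterm_pp_ok": d.cterm_pp_ok,
                "passed": d.passed,
            }
            for d in decisions
        ]
    )
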