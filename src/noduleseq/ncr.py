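"""Nodule-specific cysteine-rich (NCR) peptide candidate scanning.

NCR peptides are short secreted defensin-like peptides of indeterminate
nodules, characterized by 4 or 6 conserved cysteines in the mature region, a
cleavable N-terminal signal peptide, and a short precursor (< 150 residues).
This module scans protein sequences for that architecture, predicts the
signal peptide with a documented hydropathy heuristic, computes standard
physicochemical parameters (MW, pI, net charge, GRAVY), and adjudicates each
record with an explicit verdict and reason. Homology searches, conserved
domain lookups, localization predictors and 3D structure are out of scope;
their outputs may be supplied as external pass-through annotation columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

#: Kyte-Doolittle hydropathy index.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Average residue masses of the free amino acids (Da); peptide MW subtracts
#: one water (18.01528 Da) per bond.
AA_MASS = {
    "A": 89.0932, "R": 174.201, "N": 132.1179, "D": 133.1027, "C": 121.158,
    "Q": 146.1445, "E": 147.1293, "G": 75.0666, "H": 155.1546, "I": 131.1729,
    "L": 131.1729, "K": 146.1876, "M": 149.2113, "F": 165.1891, "P": 115.1305,
    "S": 105.0926, "T": 119.1192, "W": 204.2252, "Y": 181.1885, "V": 117.1463,
    "X": 110.0,  # unknown residue; flagged approximate
}
WATER = 18.01528

#: EMBOSS-style pKa values for the Henderson-Hasselbalch charge model.
PKA = {
    "nterm": 8.6, "cterm": 3.6,
    "K": 10.8, "R": 12.5, "H": 6.5,  # basic side chains
    "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,  # acidic side chains
}

IUPAC_AA = set("ACDEFGHIKLMNPQRSTVWYX")
SMALL_RESIDUES = set("AGSCT")


@dataclass(frozen=True)
class CysteinePattern:
    """Conserved-cysteine grammar: cysteine count and allowed inter-cysteine gaps."""

    name: str
    n_cys: int
    spacing_bounds: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if len(self.spacing_bounds) != self.n_cys - 1:
            raise InputError("spacing_bounds must have n_cys - 1 entries")
        for lo, hi in self.spacing_bounds:
            if lo < 0 or hi < lo:
                raise InputError("spacing bounds must be ordered and non-negative")


#: Default grammar: C-X(4..12)-C-X(8..30)-C-X(3..12)-C for four cysteines;
#: the six-cysteine form inserts two extra cysteines at X(1..12) gaps.
PATTERN_4C = CysteinePattern("4C", 4, ((4, 12), (8, 30), (3, 12)))
PATTERN_6C = CysteinePattern("6C", 6, ((4, 12), (1, 12), (8, 30), (1, 12), (3, 12)))
DEFAULT_PATTERNS = (PATTERN_4C, PATTERN_6C)

MAX_LENGTH = 150


@dataclass
class SignalPeptideCall:
    present: bool
    cleavage: int | None = None  # 0-based index of the first mature residue
    reason: str = ""


def detect_signal_peptide(
    sequence: str,
    min_window: int = 7,
    hydropathy_threshold: float = 1.6,
    search_len: int = 30,
    cleavage_range: tuple[int, int] = (14, 34),
) -> SignalPeptideCall:
    """Heuristic signal-peptide call from N-terminal hydropathy.

    Present iff the first ``search_len`` residues contain a window of
    ``min_window`` consecutive residues with mean Kyte-Doolittle hydropathy
    >= ``hydropathy_threshold``. The cleavage position (start of the mature
    region, 0-based) is the first small residue (A/G/S/C/T) after that window
    within ``cleavage_range``; failing that, the window end + 5.
    """
    if len(sequence) < 20:
        return SignalPeptideCall(False, None, "too short")
    head = sequence[:search_len]
    kd = np.array([KYTE_DOOLITTLE.get(a, 0.0) for a in head])
    window_end = None
    for i in range(0, len(head) - min_window + 1):
        if kd[i : i + min_window].mean() >= hydropathy_threshold:
            window_end = i + min_window - 1
            break
    if window_end is None:
        return SignalPeptideCall(False, None, "no hydrophobic stretch")
    lo, hi = cleavage_range
    for j in range(max(window_end + 1, lo), min(hi + 1, len(sequence))):
        if sequence[j] in SMALL_RESIDUES:
            return SignalPeptideCall(True, j, "")
    cleavage = min(window_end + 5, len(sequence) - 1)
    return SignalPeptideCall(True, cleavage, "no small residue; window end + 5")


def _charge_at(ph: float, seq: str) -> float:
    pos = 1.0 / (1.0 + 10.0 ** (ph - PKA["nterm"]))
    neg = -1.0 / (1.0 + 10.0 ** (PKA["cterm"] - ph))
    for aa in seq:
        if aa in ("K", "R", "H"):
            pos += 1.0 / (1.0 + 10.0 ** (ph - PKA[aa]))
        elif aa in ("D", "E", "C", "Y"):
            neg -= 1.0 / (1.0 + 10.0 ** (PKA[aa] - ph))
    return pos + neg


def compute_physicochemical(sequence: str) -> dict:
    """Molecular weight, isoelectric point, net charge at pH 7, and GRAVY.

    pI is solved by bisection on the Henderson-Hasselbalch net charge. An X
    in the sequence makes MW/pI approximate (flagged).
    """
    seq = sequence.upper()
    if not seq or not set(seq) <= IUPAC_AA:
        raise InputError(f"invalid amino-acid sequence: {sequence[:20]!r}")
    mw = sum(AA_MASS[a] for a in seq) - (len(seq) - 1) * WATER
    lo, hi = 0.0, 14.0
    for _ in range(60):
        mid = (lo + hi) / 2.0
        if _charge_at(mid, seq) > 0:
            lo = mid
        else:
            hi = mid
    pi = (lo + hi) / 2.0
    gravy = float(np.mean([KYTE_DOOLITTLE.get(a, 0.0) for a in seq]))
    return {
        "mw": float(mw),
        "pi": float(pi),
        "net_charge_ph7": float(_charge_at(7.0, seq)),
        "gravy": gravy,
        "approximate": "X" in seq,
    }


@dataclass
class NcrCandidate:
    seq_id: str
    length: int
    cys_positions: list[int] = field(default_factory=list)  # 0-based, in the scanned region
    matched_pattern: str = "none"  # 4C / 6C / none
    signal_peptide: bool = False
    cleavage: int | None = None
    scanned_region: str = "full"  # mature / full
    mw: float | None = None
    pi: float | None = None
    net_charge_ph7: float | None = None
    gravy: float | None = None
    verdict: str = "excluded"  # confirmed / unconfirmed / excluded
    reason: str = ""


def scan_ncr_candidates(
    proteins,
    patterns=DEFAULT_PATTERNS,
    max_length: int = MAX_LENGTH,
    signal_overrides: dict[str, bool] | None = None,
) -> list[NcrCandidate]:
    """Scan protein records for NCR-like architecture.

    ``proteins`` is an iterable of (id, sequence) pairs or Biopython
    SeqRecords. A record is confirmed iff its mature region (after the
    predicted cleavage site; the full sequence when no signal peptide is
    called) contains exactly 4 or 6 cysteines with consecutive gaps inside
    the pattern bounds, the precursor is shorter than ``max_length`` residues,
    and a signal peptide is present. Sequences containing X that otherwise
    pass are left unconfirmed (physicochemistry is approximate). Every record
    receives exactly one verdict with a reason.

    ``signal_overrides`` maps seq_id -> bool and bypasses the heuristic
    (external SignalP-style evidence used verbatim).
    """
    out: list[NcrCandidate] = []
    for rec in proteins:
        sid, seq = (rec[0], rec[1]) if isinstance(rec, tuple) else (rec.id, str(rec.seq))
        seq = seq.upper()
        cand = NcrCandidate(seq_id=sid, length=len(seq))
        if not seq or not set(seq) <= IUPAC_AA:
            cand.verdict, cand.reason = "excluded", "invalid sequence"
            out.append(cand)
            continue

        if signal_overrides is not None and sid in signal_overrides:
            sp = SignalPeptideCall(bool(signal_overrides[sid]), None, "external override")
        else:
            sp = detect_signal_peptide(seq)
        cand.signal_peptide, cand.cleavage = sp.present, sp.cleavage

        if sp.present and sp.cleavage is not None:
            region, cand.scanned_region = seq[sp.cleavage :], "mature"
        else:
            region, cand.scanned_region = seq, "full"
        cys = [i for i, a in enumerate(region) if a == "C"]
        cand.cys_positions = cys

        matched = None
        for pat in patterns:
            if len(cys) == pat.n_cys:
                gaps = [cys[i + 1] - cys[i] - 1 for i in range(len(cys) - 1)]
                if all(lo <= g <= hi for g, (lo, hi) in zip(gaps, pat.spacing_bounds)):
                    matched = pat
                break
        cand.matched_pattern = matched.name if matched else "none"

        phys = compute_physicochemical(seq)
        cand.mw, cand.pi = phys["mw"], phys["pi"]
        cand.net_charge_ph7, cand.gravy = phys["net_charge_ph7"], phys["gravy"]

        if matched is None:
            if len(cys) not in {p.n_cys for p in patterns}:
                cand.verdict, cand.reason = "excluded", "cysteine count"
            else:
                cand.verdict, cand.reason = "excluded", "spacing"
        elif len(seq) >= max_length:
            cand.verdict, cand.reason = "excluded", "length"
        elif not sp.present:
            cand.verdict, cand.reason = "excluded", "signal peptide"
        elif phys["approximate"]:
            cand.verdict, cand.reason = "unconfirmed", "ambiguous residues"
        else:
            cand.verdict, cand.reason = "confirmed", ""
        out.append(cand)
    return out


def candidates_to_frame(candidates: list[NcrCandidate]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        rows.append(
            {
                "seq_id": c.seq_id,
                "length": c.length,
                "matched_pattern": c.matched_pattern,
                "n_cys": len(c.cys_positions),
                "cys_positions": ",".join(map(str, c.cys_positions)),
                "signal_peptide": "present" if c.signal_peptide else "absent",
                "cleavage": c.cleavage if c.cleavage is not None else "",
                "scanned_region": c.scanned_region,
                "mw": None if c.mw is None else round(c.mw, 2),
                "pi": None if c.pi is None else round(c.pi, 3),
                "net_charge_ph7": None if c.net_charge_ph7 is None else round(c.net_charge_ph7, 3),
                "gravy": None if c.gravy is None else round(c.gravy, 4),
                "verdict": c.verdict,
                "reason": c.reason,
            }
        )
    return pd.DataFrame(rows)


def adjudicate_ncr(
    candidates: list[NcrCandidate],
    de_results: pd.DataFrame | None = None,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Join candidates with DE status and summarize verdicts.

    Candidates whose gene was excluded as low counts are marked as omitted
    from the DEG analysis; unmatched ids are reported in the summary.
    """
    import warnings

    df = candidates_to_frame(candidates)
    report: dict = {
        "n_input": len(df),
        "verdict_counts": df["verdict"].value_counts().to_dict() if len(df) else {},
    }
    if de_results is not None and len(df):
        de = de_results.reindex(df["seq_id"])
        df["de_status"] = de["status"].fillna("not_in_matrix").to_numpy()
        df["padj"] = de["padj"].to_numpy()
        df["log2fc"] = de["log2fc"].to_numpy()
        df["differentially_expressed"] = (
            (df["padj"] < alpha) & (df["log2fc"].abs() > lfc_threshold)
        ).fillna(False)
        df["deg_note"] = np.where(
            df["de_status"] == "low_count", "omitted from the DEG analysis", ""
        )
        unmatched = df.loc[df["de_status"] == "not_in_matrix", "seq_id"].tolist()
        if unmatched:
            warnings.warn(f"{len(unmatched)} candidate ids not found in the DE table")
        report["unmatched_ids"] = unmatched
        report["n_confirmed_de"] = int(
            ((df["verdict"] == "confirmed") & df["differentially_expressed"]).sum()
        )
        report["de_status_counts"] = df["de_status"].value_counts().to_dict()
    return df, report
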