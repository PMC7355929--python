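"""Marker annotation ladder for negative-mode LC-HRMS features.

Given an observed (m/z, retention time) feature and a list of candidate
compounds (name, molecular formula, optional predicted retention time,
optional reference MS/MS spectrum), the ladder proceeds:

1. exact-mass search on the deprotonated ion [M-H]- within a mass tolerance
   (default 5 mDa),
2. theoretical isotope-pattern simulation and a dot-product fit score
   (mSigma-like; accept below 100),
3. MS/MS spectral similarity (cosine over square-root intensities;
   accept at >= 0.7, or >= 3 matched fragments when the reference library
   carries no intensities),
4. retention-time plausibility (reject when the predicted-vs-observed
   error reaches 1.8 min),
5. assignment of a tiered identification-confidence level
   (1, 2a, 2b, 3, 4, 5: confirmed standard down to exact mass only).

The isotope-fit score is cosine-based; vendor mSigma values are proprietary
and only the accept/reject threshold semantics are mapped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from oliveauth.isotopes import ISOTOPES, MONOISOTOPIC_MASS, PROTON_MASS

__all__ = [
    "MolecularFormula",
    "IsotopePattern",
    "MSMSSpectrum",
    "CandidateCompound",
    "CandidateAnnotation",
    "AnnotationEvidence",
    "parse_formula",
    "monoisotopic_mass",
    "mz_deprotonated",
    "mass_error",
    "isotope_pattern",
    "isotope_fit",
    "msms_similarity",
    "search_candidates",
    "assign_level",
]

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")

#: identification-confidence tiers, best first
LEVELS = ("1", "2a", "2b", "3", "4", "5")


@dataclass(frozen=True)
class MolecularFormula:
    """Element -> count map, e.g. ``{"C": 6, "H": 6, "O": 2}`` for catechol."""

    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("formula must contain at least one element")
        for el, n in self.counts.items():
            if el not in ISOTOPES:
                raise ValueError(f"unknown element {el!r}")
            if n < 0:
                raise ValueError(f"negative count for element {el!r}")

    def __str__(self) -> str:
        return "".join(
            f"{el}{n if n != 1 else ''}" for el, n in self.counts.items() if n > 0
        )


def parse_formula(formula: str | MolecularFormula) -> MolecularFormula:
    """Parse a Hill-style formula string such as ``"C25H32O13"``."""
    if isinstance(formula, MolecularFormula):
        return formula
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        el, num = m.group(1), m.group(2)
        if el not in ISOTOPES:
            raise ValueError(f"unknown element {el!r} in formula {formula!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return MolecularFormula(counts)


def monoisotopic_mass(formula: str | MolecularFormula) -> float:
    """Neutral monoisotopic mass in Da (sum of most-abundant-isotope masses)."""
    f = parse_formula(formula)
    return float(sum(MONOISOTOPIC_MASS[el] * n for el, n in f.counts.items()))


def mz_deprotonated(formula: str | MolecularFormula) -> float:
    """Theoretical m/z of the deprotonated ion [M-H]- in Da."""
    f = parse_formula(formula)
    if f.counts.get("H", 0) < 1:
        raise ValueError("formula has no hydrogen to remove")
    return monoisotopic_mass(f) - PROTON_MASS


def mass_error(theoretical: float, observed: float) -> tuple[float, float]:
    """Mass error as (mDa, ppm), sign = theoretical - observed.

    With this convention an observed 109.0299 against theoretical 109.0295
    gives -0.4 mDa.
    """
    if theoretical <= 0 or observed <= 0:
        raise ValueError("m/z values must be positive")
    mda = (theoretical - observed) * 1000.0
    return mda, mda * 1000.0 / theoretical


@dataclass(frozen=True)
class IsotopePattern:
    """Isotopologue peaks as (m/z, relative abundance), base peak = 100."""

    peaks: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError("empty isotope pattern")
        if abs(max(a for _, a in self.peaks) - 100.0) > 1e-9:
            raise ValueError("base peak abundance must be 100")

    @property
    def mz(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks])

    @property
    def abundance(self) -> np.ndarray:
        return np.array([a for _, a in self.peaks])


def _convolve(
    a: list[tuple[float, float]], b: list[tuple[float, float]], prune: float
) -> list[tuple[float, float]]:
    """Convolve two (mass, probability) distributions, merging within 1 mDa."""
    acc: dict[int, tuple[float, float]] = {}
    for ma, pa in a:
        for mb, pb in b:
            p = pa * pb
            if p < prune:
                continue
            key = round((ma + mb) * 1000)  # 1 mDa aggregation grid
            if key in acc:
                m0, p0 = acc[key]
                acc[key] = ((m0 * p0 + (ma + mb) * p) / (p0 + p), p0 + p)
            else:
                acc[key] = (ma + mb, p)
    return sorted(acc.values())


def isotope_pattern(
    formula: str | MolecularFormula,
    abundance_threshold: float = 0.01,
    charge_h_loss: int = 0,
) -> IsotopePattern:
    """Theoretical isotope pattern by polynomial expansion.

    Parameters
    ----------
    abundance_threshold : relative-abundance cutoff in percent of base peak.
    charge_h_loss : number of protons removed (1 for the [M-H]- pattern).
    """
    f = parse_formula(formula)
    counts = dict(f.counts)
    if charge_h_loss:
        if counts.get("H", 0) < charge_h_loss:
            raise ValueError("not enough hydrogens for deprotonation")
        counts["H"] -= charge_h_loss
    dist: list[tuple[float, float]] = [(0.0, 1.0)]
    prune = 1e-12
    for el, n in counts.items():
        atom = ISOTOPES[el]
        # repeated-squaring convolution of the single-atom distribution
        power = atom
        k = n
        while k:
            if k & 1:
                dist = _convolve(dist, power, prune)
            k >>= 1
            if k:
                power = _convolve(power, power, prune)
    if charge_h_loss:
        dist = [(m - charge_h_loss * PROTON_MASS, p) for m, p in dist]
    base = max(p for _, p in dist)
    peaks = sorted(
        (m, 100.0 * p / base)
        for m, p in dist
        if 100.0 * p / base >= abundance_threshold
    )
    return IsotopePattern(tuple(peaks))


def isotope_fit(theoretical: IsotopePattern, observed: IsotopePattern,
                mz_tol: float = 0.005) -> float:
    """Dot-product (cosine) isotope-pattern fit, scaled so lower is better.

    Peaks are matched within ``mz_tol`` Da; unmatched peaks on either side
    count as zeros.  Score = 1000 * (1 - cosine): 0 for identical patterns,
    1000 for disjoint ones.  Accept below 100.
    """
    t_used = [False] * len(theoretical.peaks)
    pairs: list[tuple[float, float]] = []  # aligned (theoretical, observed)
    o_matched = [False] * len(observed.peaks)
    for i, (om, oa) in enumerate(observed.peaks):
        best, best_d = None, mz_tol
        for j, (tm, _) in enumerate(theoretical.peaks):
            d = abs(tm - om)
            if not t_used[j] and d <= best_d:
                best, best_d = j, d
        if best is not None:
            t_used[best] = True
            o_matched[i] = True
            pairs.append((theoretical.peaks[best][1], oa))
    for j, used in enumerate(t_used):
        if not used:
            pairs.append((theoretical.peaks[j][1], 0.0))
    for i, matched in enumerate(o_matched):
        if not matched:
            pairs.append((0.0, observed.peaks[i][1]))
    t = np.array([p[0] for p in pairs])
    o = np.array([p[1] for p in pairs])
    denom = np.linalg.norm(t) * np.linalg.norm(o)
    cosine = float(t @ o / denom) if denom > 0 else 0.0
    return 1000.0 * (1.0 - min(cosine, 1.0))


@dataclass(frozen=True)
class MSMSSpectrum:
    """Fragment spectrum as (m/z, intensity) peaks; intensities >= 0."""

    peaks: tuple[tuple[float, float], ...]
    precursor_mz: float | None = None

    def __post_init__(self) -> None:
        if any(i < 0 for _, i in self.peaks):
            raise ValueError("negative fragment intensity")

    @classmethod
    def from_pairs(cls, text: str) -> "MSMSSpectrum":
        """Parse ``"mz:intensity;mz:intensity;..."`` (intensity optional)."""
        peaks = []
        for token in text.split(";"):
            token = token.strip()
            if not token:
                continue
            if ":" in token:
                mz, inten = token.split(":")
                peaks.append((float(mz), float(inten)))
            else:
                peaks.append((float(token), 1.0))
        return cls(tuple(peaks))

    @property
    def has_intensities(self) -> bool:
        vals = {i for _, i in self.peaks}
        return len(vals) > 1


def msms_similarity(
    a: MSMSSpectrum, b: MSMSSpectrum, tol: float = 0.01
) -> tuple[float, int]:
    """Cosine similarity over sqrt-intensity peak vectors, plus match count.

    Greedy matching: peak pairs within ``tol`` Da are matched highest
    intensity product first; unmatched peaks enter the vectors as zeros.
    Symmetric and bounded in [0, 1].
    """
    if tol < 0:
        raise ValueError("negative tolerance")
    if not a.peaks or not b.peaks:
        raise ValueError("empty spectrum")
    cand = [
        (ia, ib, np.sqrt(pa[1] * pb[1]))
        for ia, pa in enumerate(a.peaks)
        for ib, pb in enumerate(b.peaks)
        if abs(pa[0] - pb[0]) <= tol
    ]
    cand.sort(key=lambda c: (-c[2], c[0], c[1]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches: list[tuple[int, int]] = []
    for ia, ib, _ in cand:
        if ia not in used_a and ib not in used_b:
            used_a.add(ia)
            used_b.add(ib)
            matches.append((ia, ib))
    va, vb = [], []
    for ia, ib in matches:
        va.append(np.sqrt(a.peaks[ia][1]))
        vb.append(np.sqrt(b.peaks[ib][1]))
    for ia, p in enumerate(a.peaks):
        if ia not in used_a:
            va.append(np.sqrt(p[1]))
            vb.append(0.0)
    for ib, p in enumerate(b.peaks):
        if ib not in used_b:
            va.append(0.0)
            vb.append(np.sqrt(p[1]))
    va_arr, vb_arr = np.array(va), np.array(vb)
    denom = np.linalg.norm(va_arr) * np.linalg.norm(vb_arr)
    score = float(va_arr @ vb_arr / denom) if denom > 0 else 0.0
    return min(score, 1.0), len(matches)


@dataclass
class CandidateCompound:
    """Entry of a candidate list used for the exact-mass search."""

    name: str
    formula: str
    predicted_rt: float | None = None
    reference_msms: MSMSSpectrum | None = None
    reference_standard: bool = False


@dataclass
class AnnotationEvidence:
    """Evidence flags feeding the identification-confidence ladder."""

    reference_standard: bool = False
    library_msms_cosine: float | None = None
    library_has_intensities: bool = True
    n_matched_fragments: int = 0
    isomer_indistinguishable: bool = False
    in_silico_or_literature_msms: bool = False
    rt_prioritization: bool = False
    unique_formula: bool = False
    isotope_fit: float | None = None
    exact_mass_match: bool = False


@dataclass
class CandidateAnnotation:
    """Scored annotation of one observed feature by one candidate."""

    name: str
    formula: str
    theoretical_mz: float
    mass_error_mda: float
    mass_error_ppm: float
    isotope_fit: float | None = None
    msms_score: float | None = None
    n_matched_fragments: int = 0
    rt_error_min: float | None = None
    level: str | None = None
    in_source_fragment_of: str | None = None


def assign_level(evidence: AnnotationEvidence) -> str:
    """Identification-confidence tier from the evidence flags.

    1  confirmed by reference standard;
    2a library MS/MS match (cosine >= 0.7, or >= 3 matched fragments when
       the library spectrum has no intensities);
    2b library evidence that cannot distinguish isomers;
    3  literature / in-silico MS/MS or retention-time prioritization only;
    4  unequivocal molecular formula (mass + isotope fit < 100) only;
    5  exact mass only.
    """
    if evidence.reference_standard:
        return "1"
    library_match = (
        evidence.library_msms_cosine is not None
        and evidence.library_msms_cosine >= 0.7
    ) or (not evidence.library_has_intensities and evidence.n_matched_fragments >= 3)
    if library_match:
        return "2b" if evidence.isomer_indistinguishable else "2a"
    if evidence.in_silico_or_literature_msms or evidence.rt_prioritization:
        return "3"
    if (
        evidence.unique_formula
        and evidence.isotope_fit is not None
        and evidence.isotope_fit < 100
    ):
        return "4"
    if evidence.exact_mass_match:
        return "5"
    raise ValueError("no usable evidence: not even an exact-mass match")


def search_candidates(
    observed_mz: float,
    rt: float | None,
    candidates: list[CandidateCompound],
    mz_tol: float = 0.005,
    rt_max_err: float = 1.8,
    observed_pattern: IsotopePattern | None = None,
    observed_msms: MSMSSpectrum | None = None,
    msms_tol: float = 0.01,
) -> list[CandidateAnnotation]:
    """Exact-mass candidate search on [M-H]- with optional rt/isotope/MS2 evidence.

    Retains candidates with |mass error| < ``mz_tol`` Da; drops those whose
    predicted-vs-observed retention-time error reaches ``rt_max_err`` min.
    Ranked by |mass error|, then isotope fit when an observed pattern is given.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    hits: list[CandidateAnnotation] = []
    for cand in candidates:
        theo = mz_deprotonated(cand.formula)
        mda, ppm = mass_error(theo, observed_mz)
        if abs(mda) / 1000.0 >= mz_tol:
            continue
        rt_err = None
        if rt is not None and cand.predicted_rt is not None:
            rt_err = rt - cand.predicted_rt
            if abs(rt_err) >= rt_max_err:
                continue
        ann = CandidateAnnotation(
            name=cand.name,
            formula=str(parse_formula(cand.formula)),
            theoretical_mz=theo,
            mass_error_mda=mda,
            mass_error_ppm=ppm,
            rt_error_min=rt_err,
        )
        if observed_pattern is not None:
            theo_pattern = isotope_pattern(cand.formula, charge_h_loss=1)
            ann.isotope_fit = isotope_fit(theo_pattern, observed_pattern)
        if observed_msms is not None and cand.reference_msms is not None:
            ann.msms_score, ann.n_matched_fragments = msms_similarity(
                observed_msms, cand.reference_msms, tol=msms_tol
            )
        evidence = AnnotationEvidence(
            reference_standard=cand.reference_standard,
            library_msms_cosine=ann.msms_score,
            library_has_intensities=(
                cand.reference_msms.has_intensities
                if cand.reference_msms is not None
                else True
            ),
            n_matched_fragments=ann.n_matched_fragments,
            rt_prioritization=rt_err is not None,
            unique_formula=ann.isotope_fit is not None,
            isotope_fit=ann.isotope_fit,
            exact_mass_match=True,
        )
        ann.level = assign_level(evidence)
        hits.append(ann)
    hits.sort(
        key=lambda h: (
            abs(h.mass_error_mda),
            h.isotope_fit if h.isotope_fit is not None else np.inf,
        )
    )
    return hits
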