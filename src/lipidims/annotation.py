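"""Adduct- and isotope-aware annotation of imaging-MS ions against a
lipid library, with tiered confidence scoring.

The library emulates the output of an LC-MS/MS identification experiment:
lipid records with shorthand names, neutral monoisotopic masses (or
elemental compositions) and database-evidence flags. Observed target ions
are matched to every protonated, sodiated, potassiated, dehydrated and
single-13C adduct form within a ppm tolerance (100 ppm by default, sized
for calibration drift across multi-month MALDI acquisitions), then scored:

    tier i   manually annotated ID (highest confidence),
    tier ii  LipidMatch and LipidBlast database overlap,
    tier iii highly scored LipidMatch ID without LipidBlast support,
    tier iv  excluded: low database score, odd total fatty-acid carbon
             count, or an adduct combination implausible for singly
             charged positive ions; every tier-iv hit lists its reasons.

One observed ion may retain several tier-assigned hits; ambiguity is
reported, not resolved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chem
from .nomenclature import LipidParseError, parse_shorthand
from .spectra import TargetList

TIERS = ("i", "ii", "iii", "iv")


@dataclass
class LipidRecord:
    """One reference lipid with database-evidence metadata."""

    name: str
    neutral_mass: float | None = None
    formula: str | None = None
    headgroup: str | None = None
    manual_id: bool = False
    lipidmatch_hit: bool = False
    lipidmatch_score_high: bool = False
    lipidblast_hit: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.neutral_mass is None:
            if self.formula is None:
                raise ValueError(
                    f"{self.name!r}: need neutral_mass or elemental formula"
                )
            self.neutral_mass = chem.formula_mass(self.formula)
        if self.neutral_mass <= 0:
            raise ValueError(f"{self.name!r}: neutral_mass must be positive")
        if self.headgroup is None:
            try:
                self.headgroup = parse_shorthand(self.name).headgroup
            except LipidParseError:
                self.headgroup = ""

    @property
    def parsed(self):
        return parse_shorthand(self.name)


@dataclass
class LipidLibrary:
    records: list[LipidRecord]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_csv(self, path: str | Path) -> None:
        rows = [{
            "name": r.name,
            "headgroup": r.headgroup,
            "formula_or_mass": r.formula or f"{r.neutral_mass:.6f}",
            "neutral_mass": f"{r.neutral_mass:.6f}",
            "manual_id": int(r.manual_id),
            "lipidmatch_hit": int(r.lipidmatch_hit),
            "lipidmatch_score_high": int(r.lipidmatch_score_high),
            "lipidblast_hit": int(r.lipidblast_hit),
        } for r in self.records]
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LipidLibrary":
        df = pd.read_csv(path, keep_default_na=False)
        records = []
        for row in df.itertuples(index=False):
            fm = str(row.formula_or_mass)
            try:
                mass, formula = float(fm), None
            except ValueError:
                mass, formula = None, fm
            records.append(LipidRecord(
                name=row.name, neutral_mass=mass, formula=formula,
                headgroup=row.headgroup or None,
                manual_id=bool(int(row.manual_id)),
                lipidmatch_hit=bool(int(row.lipidmatch_hit)),
                lipidmatch_score_high=bool(int(row.lipidmatch_score_high)),
                lipidblast_hit=bool(int(row.lipidblast_hit)),
            ))
        return cls(records)


def theoretical_mz(record: LipidRecord, adduct: str) -> float:
    """Theoretical m/z of a +1 adduct ion of a library lipid."""
    return chem.adduct_mz(record.neutral_mass, adduct)


@dataclass
class AnnotationHit:
    bin_id: str
    observed_mz: float
    lipid: str
    adduct: str
    theoretical_mz: float
    ppm_error: float
    tier: str = ""
    reasons: tuple[str, ...] = ()


def match_ions(
    targets: TargetList,
    library: LipidLibrary,
    tolerance_ppm: float = 100.0,
    adducts: tuple[str, ...] | None = None,
) -> list[AnnotationHit]:
    """Match every observed target against every (lipid, adduct) pair.

    A hit is retained when |observed - theoretical| / theoretical * 1e6
    <= tolerance. One target may receive multiple hits; the result is
    sorted by absolute ppm error within each target.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be > 0")
    if not len(library):
        warnings.warn("empty lipid library; no annotations")
        return []
    if adducts is None:
        adducts = tuple(chem.ADDUCT_DELTAS)

    # flat theoretical table, sorted for a windowed sweep
    theo = []
    for rec in library:
        for adduct in adducts:
            theo.append((chem.adduct_mz(rec.neutral_mass, adduct), rec.name, adduct))
    theo.sort()
    theo_mz = np.array([t[0] for t in theo])

    hits: list[AnnotationHit] = []
    for tgt in targets.targets.itertuples(index=False):
        obs = float(tgt.mz_center)
        half = theo_mz * tolerance_ppm * 1e-6
        lo = np.searchsorted(theo_mz + half, obs, side="left")
        hi = np.searchsorted(theo_mz - half, obs, side="right")
        cand = []
        for j in range(lo, hi):
            tmz, name, adduct = theo[j]
            ppm = chem.ppm_error(obs, tmz)
            if abs(ppm) <= tolerance_ppm:
                cand.append(AnnotationHit(
                    bin_id=tgt.bin_id, observed_mz=obs, lipid=name,
                    adduct=adduct, theoretical_mz=tmz, ppm_error=ppm,
                ))
        cand.sort(key=lambda h: abs(h.ppm_error))
        hits.extend(cand)
    return hits


def score_tiers(
    hits: list[AnnotationHit], library: LipidLibrary
) -> list[AnnotationHit]:
    """Assign confidence tiers i-iv to matched hits.

    Precedence: manual ID -> tier i; LipidMatch AND LipidBlast -> tier ii;
    high-scoring LipidMatch without LipidBlast -> tier iii; otherwise tier
    iv (excluded) with explicit reasons — low database score, odd total
    fatty-acid carbon count, or a non-protonated-only adduct pattern
    (cation adducts of a lipid whose only supported form is protonated
    are flagged, emulating the doubly-charged-form sanity check).
    """
    by_name = {rec.name: rec for rec in library}
    scored = []
    for hit in hits:
        rec = by_name.get(hit.lipid)
        if rec is None:
            raise KeyError(f"hit references unknown library lipid {hit.lipid!r}")
        reasons: list[str] = []
        try:
            odd = rec.parsed.odd_chain
        except LipidParseError:
            odd = False
        if odd:
            reasons.append("odd_chain")
        if not (rec.manual_id or rec.lipidmatch_hit or rec.lipidmatch_score_high):
            reasons.append("low_lipidmatch_score")
        implausible = rec.meta.get("protonated_only", False) and hit.adduct not in (
            "M+H", "M+H+13C", "M+H-H2O", "M+H-H2O+13C"
        )
        if implausible:
            reasons.append("implausible_adduct")

        if rec.manual_id:
            # manual annotation takes precedence over every other indicator
            tier = "i"
            reasons = []
        elif reasons:
            tier = "iv"
        elif rec.lipidmatch_hit and rec.lipidblast_hit:
            tier = "ii"
        elif rec.lipidmatch_score_high and not rec.lipidblast_hit:
            tier = "iii"
        else:
            tier = "iv"
            reasons.append("low_lipidmatch_score")
        scored.append(AnnotationHit(
            hit.bin_id, hit.observed_mz, hit.lipid, hit.adduct,
            hit.theoretical_mz, hit.ppm_error, tier, tuple(reasons),
        ))
    return scored


def hits_to_frame(hits: list[AnnotationHit]) -> pd.DataFrame:
    return pd.DataFrame([{
        "bin_id": h.bin_id, "observed_mz": h.observed_mz, "lipid": h.lipid,
        "adduct": h.adduct, "theoretical_mz": h.theoretical_mz,
        "ppm_error": h.ppm_error, "tier": h.tier,
        "reasons": ";".join(h.reasons),
    } for h in hits])


@dataclass
class ConsensusLibraryBin:
    """One 0.2-Da-wide half-open m/z consensus bin of library records."""

    bin_index: int
    mz_low: float
    mz_high: float
    members: list[LipidRecord]

    @property
    def ambiguous(self) -> bool:
        return len(self.members) > 1


def build_consensus_library(
    records: list[LipidRecord],
    bin_width: float = 0.2,
    mz_of: str = "M+H",
) -> list[ConsensusLibraryBin]:
    """Collapse library records into half-open m/z bins of ``bin_width``
    (retention-time information discarded), the consensus form used to
    compare LC-MS identifications across runs. Each record lands in
    exactly one bin; multi-member bins are flagged ambiguous."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    buckets: dict[int, list[LipidRecord]] = {}
    for rec in records:
        mz = chem.adduct_mz(rec.neutral_mass, mz_of) if mz_of else rec.neutral_mass
        k = int(np.floor(mz / bin_width))
        buckets.setdefault(k, []).append(rec)
    return [
        ConsensusLibraryBin(k, k * bin_width, (k + 1) * bin_width, members)
        for k, members in sorted(buckets.items())
    ]
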