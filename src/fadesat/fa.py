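"""Fatty-acid nomenclature and desaturation indices.

Fatty acids are named ``C:D`` (chain length : double bonds) with an optional
omega class giving the position of the first double bond counted from the
methyl end, e.g. ``16:1ω7``.  Composition profiles are maps from FA label to
percent by weight (wt%).  Two summary indices are computed from a profile:

* the Δ9-desaturation index (Δ9-DI), the ratio of five Δ9-pathway
  monounsaturated FAs to their three saturated precursors — a proxy for
  endogenous stearoyl-CoA (Δ9) desaturase activity; and
* the double-bond index (DBI), the wt%-weighted mean number of double bonds
  over *all* FAs, which also picks up dietary polyunsaturates.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

__all__ = [
    "FattyAcid",
    "FAProfile",
    "Section",
    "FAParseError",
    "ProfileError",
    "parse_fa_label",
    "delta9_desaturation_index",
    "double_bond_index",
    "validate_profile",
    "DELTA9_MUFAS",
    "DELTA9_SFAS",
]

logger = logging.getLogger(__name__)

#: numerator (Δ9-pathway MUFAs) and denominator (precursor SFAs) of the Δ9-DI
DELTA9_MUFAS = ("14:1ω5", "16:1ω7", "16:1ω9", "18:1ω9", "18:1ω7")
DELTA9_SFAS = ("14:0", "16:0", "18:0")


class FAParseError(ValueError):
    """A fatty-acid label could not be parsed."""


class ProfileError(ValueError):
    """A composition profile violates a hard constraint (e.g. negative wt%)."""


class Section(str, Enum):
    """Adipose-tissue section a profile was measured on."""

    outer = "outer"
    whole = "whole"
    white_adipose = "white_adipose"
    unknown = "unknown"


# Accepted spellings of the omega class.  ``16:1ω7`` is canonical; ``w7``,
# ``n-7`` and ``(n-7)`` are common journal dialects.  Extend via
# ``OMEGA_DIALECTS`` before parsing if a source uses another convention.
OMEGA_DIALECTS: list[str] = [
    r"ω(?P<omega>\d+)",
    r"w(?P<omega>\d+)",
    r"n-?(?P<omega>\d+)",
    r"\(n-?(?P<omega>\d+)\)",
]

# branched-chain prefixes (iso/anteiso); parsed, saturated, never in Δ9-DI
_PREFIX_RE = r"(?:(?P<prefix>iso|anteiso|i|ai)-?)?"


def _omega_regex() -> re.Pattern[str]:
    alts = "|".join(f"(?:{d.replace('?P<omega>', '')})" for d in OMEGA_DIALECTS)
    return re.compile(
        _PREFIX_RE + r"(?P<carbons>\d+):(?P<bonds>\d+)\s*(?P<tail>" + alts + r")?\s*$"
    )


@dataclass(frozen=True)
class FattyAcid:
    """One fatty acid: chain length, double-bond count, optional ω class."""

    carbons: int
    double_bonds: int
    omega_position: int | None = None
    branched: bool = False

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise FAParseError(f"chain length must be ≥ 2, got {self.carbons}")
        if self.double_bonds < 0:
            raise FAParseError(f"double bonds must be ≥ 0, got {self.double_bonds}")
        if (self.double_bonds == 0) != (self.omega_position is None):
            raise FAParseError(
                "omega position must be present exactly when double_bonds > 0 "
                f"(got {self.double_bonds} bonds, ω={self.omega_position})"
            )

    @property
    def label(self) -> str:
        """Canonical label, e.g. ``16:1ω7`` or ``16:0``."""
        prefix = "iso-" if self.branched else ""
        if self.omega_position is None:
            return f"{prefix}{self.carbons}:{self.double_bonds}"
        return f"{prefix}{self.carbons}:{self.double_bonds}ω{self.omega_position}"


def parse_fa_label(label: str) -> FattyAcid:
    """Parse a fatty-acid label in any supported dialect.

    Accepts ``16:1ω7``, ``16:1w7``, ``16:1n-7`` and ``16:1(n-7)`` (all
    canonicalised to ``16:1ω7``), plain saturated labels like ``16:0``, and
    iso/anteiso branched-chain prefixes.  Raises :class:`FAParseError` naming
    the offending token otherwise.
    """
    if not label or not label.strip():
        raise FAParseError("empty fatty-acid label")
    text = label.strip()
    if ":" not in text:
        raise FAParseError(f"no ':' separator in fatty-acid label {text!r}")
    m = _omega_regex().match(text)
    if m is None:
        raise FAParseError(f"malformed fatty-acid label {text!r}")
    carbons = int(m.group("carbons"))
    bonds = int(m.group("bonds"))
    tail = m.group("tail")
    omega: int | None = None
    if tail:
        om = re.search(r"(\d+)\s*\)?\s*$", tail)
        assert om is not None
        omega = int(om.group(1))
    if bonds > 0 and omega is None:
        raise FAParseError(
            f"unsaturated fatty acid {text!r} lacks an ω position; "
            "add one (e.g. 16:1ω7) or register the dialect in OMEGA_DIALECTS"
        )
    if bonds == 0 and omega is not None:
        raise FAParseError(f"saturated fatty acid {text!r} cannot carry an ω class")
    return FattyAcid(
        carbons=carbons,
        double_bonds=bonds,
        omega_position=omega,
        branched=m.group("prefix") is not None,
    )


@dataclass
class FAProfile:
    """Per-species fatty-acid composition in percent by weight.

    ``weights`` maps canonical FA labels to wt%.  Labels are canonicalised on
    construction; two input labels collapsing to the same canonical form is an
    error (it would silently double-count mass).
    """

    species: str
    weights: dict[str, float] = field(default_factory=dict)
    section: Section = Section.unknown

    def __post_init__(self) -> None:
        canonical: dict[str, float] = {}
        for raw_label, wt in self.weights.items():
            fa = parse_fa_label(raw_label)
            if wt < 0:
                raise ProfileError(
                    f"{self.species}: negative wt% {wt} for {raw_label!r}"
                )
            if fa.label in canonical:
                raise ProfileError(
                    f"{self.species}: labels {raw_label!r} and an earlier entry both "
                    f"canonicalise to {fa.label!r}"
                )
            canonical[fa.label] = float(wt)
        self.weights = canonical
        self.section = Section(self.section)

    def get(self, label: str) -> float:
        """wt% of a fatty acid; absent FAs count as zero."""
        return self.weights.get(parse_fa_label(label).label, 0.0)

    def total(self) -> float:
        return sum(self.weights.values())

    def renormalized(self) -> "FAProfile":
        """Profile rescaled so wt% sums to exactly 100."""
        tot = self.total()
        if tot <= 0:
            raise ProfileError(f"{self.species}: cannot renormalise empty profile")
        return FAProfile(
            species=self.species,
            weights={k: v * 100.0 / tot for k, v in self.weights.items()},
            section=self.section,
        )


def delta9_desaturation_index(profile: FAProfile) -> float:
    """Δ9-desaturation index of a profile.

    (wt%14:1ω5 + wt%16:1ω7 + wt%16:1ω9 + wt%18:1ω9 + wt%18:1ω7) /
    (wt%14:0 + wt%16:0 + wt%18:0).  FAs absent from the profile contribute
    zero (logged); polyunsaturates never enter.  Raises :class:`ProfileError`
    when the saturated denominator is zero, rather than returning infinity.
    """
    missing = [
        lab for lab in (*DELTA9_MUFAS, *DELTA9_SFAS) if lab not in profile.weights
    ]
    if missing:
        logger.warning(
            "%s: formula FAs %s absent, counted as wt%% 0",
            profile.species,
            ", ".join(missing),
        )
    numerator = sum(profile.get(lab) for lab in DELTA9_MUFAS)
    denominator = sum(profile.get(lab) for lab in DELTA9_SFAS)
    if denominator == 0:
        raise ProfileError(
            f"{profile.species}: Δ9-DI undefined — saturated denominator "
            "(14:0 + 16:0 + 18:0) is zero"
        )
    return numerator / denominator


def double_bond_index(profile: FAProfile) -> float:
    """Double-bond index: Σ over all FAs of double_bonds × wt% / 100.

    Counts every FA in the profile, monounsaturated and polyunsaturated alike;
    saturated FAs contribute zero.  Unparseable labels raise at profile
    construction, so no silent skipping can occur here.
    """
    return sum(
        parse_fa_label(lab).double_bonds * wt for lab, wt in profile.weights.items()
    ) / 100.0


def validate_profile(profile: FAProfile, tolerance: float = 5.0) -> list[str]:
    """Check a profile's mass balance; returns human-readable warnings.

    Negative weights and duplicate labels are hard errors raised by
    :class:`FAProfile` itself; here only the wt% total is checked against
    100 ± ``tolerance`` (absent FAs count as zero mass).
    """
    warnings: list[str] = []
    tot = profile.total()
    if abs(tot - 100.0) > tolerance:
        warnings.append(
            f"{profile.species}: wt% total {tot:.6g} outside 100 ± {tolerance:g}"
        )
    return warnings


def profiles_to_indices(
    profiles: Iterable[FAProfile], tolerance: float = 5.0, renormalize: bool = False
) -> "pd.DataFrame":
    """Tabulate Δ9-DI and DBI for a collection of profiles.

    Returns a DataFrame with columns species, delta9_di, dbi, n_fas_used,
    warnings.  ``renormalize`` rescales each profile to a 100 wt% total first;
    the default leaves raw wt% untouched since both indices are ratios or
    weighted sums of the reported values.
    """
    import pandas as pd

    rows = []
    for prof in profiles:
        if renormalize:
            prof = prof.renormalized()
        warns = validate_profile(prof, tolerance=tolerance)
        rows.append(
            {
                "species": prof.species,
                "delta9_di": delta9_desaturation_index(prof),
                "dbi": double_bond_index(prof),
                "n_fas_used": len(prof.weights),
                "warnings": "; ".join(warns),
            }
        )
    return pd.DataFrame(rows)
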