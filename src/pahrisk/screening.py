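"""BaP-equivalent conversion and drinking-water standard screening.

A multi-analyte PAH profile is collapsed to a single benzo[a]pyrene
equivalent (BaPeq) concentration by weighting each carcinogenic analyte
with its potency equivalency factor:

    BaPeq = sum over carcinogens of  C_i * PEF_i        (ng/L)

Non-detects are resolved by a substitution policy (``zero``, ``half_dl``
or ``dl``) against the analytical detection limits.  Screening compares
BaP, total-PAH and BaPeq levels against national standards with a strict
``>`` (equality to a limit is compliant).
"""

from __future__ import annotations

from typing import Dict, Mapping, Optional

from .analytes import PEFTable, Standard
from .samples import WaterSample

ND_POLICIES = ("zero", "half_dl", "dl")


def _resolve(
    sample: WaterSample,
    analyte: str,
    nd_policy: str,
    detection_limits: Optional[Mapping[str, float]],
) -> float:
    """Numeric concentration for one analyte under the non-detect policy."""
    if analyte in sample.conc:
        return sample.conc[analyte]
    if sample.nondetect.get(analyte):
        if nd_policy == "zero":
            return 0.0
        if detection_limits is None or analyte not in detection_limits:
            raise ValueError(
                f"nd_policy {nd_policy!r} needs a detection limit for {analyte}"
            )
        dl = detection_limits[analyte]
        return 0.5 * dl if nd_policy == "half_dl" else dl
    return 0.0


def _check_policy(nd_policy: str) -> None:
    if nd_policy not in ND_POLICIES:
        raise ValueError(f"nd_policy must be one of {ND_POLICIES}, got {nd_policy!r}")


def bapeq_concentration(
    sample: WaterSample,
    pefs: Optional[PEFTable] = None,
    nd_policy: str = "zero",
    detection_limits: Optional[Mapping[str, float]] = None,
) -> float:
    """PEF-weighted BaP-equivalent concentration of a sample (ng/L).

    Every carcinogenic analyte must have been measured (a value or a
    non-detect flag); an analyte missing entirely raises ``ValueError``.
    """
    _check_policy(nd_policy)
    pefs = pefs or PEFTable()
    total = 0.0
    for analyte in sorted(pefs.carcinogenic_set):
        if not sample.measured(analyte):
            raise ValueError(
                f"carcinogenic analyte {analyte} missing from sample "
                f"{sample.village_id}/{sample.water_type}/{sample.season}"
            )
        total += pefs.pef[analyte] * _resolve(sample, analyte, nd_policy, detection_limits)
    return total


def total_pahs(
    sample: WaterSample,
    nd_policy: str = "zero",
    detection_limits: Optional[Mapping[str, float]] = None,
) -> float:
    """Unweighted sum of all 16 analyte concentrations (ng/L)."""
    _check_policy(nd_policy)
    return sum(
        _resolve(sample, a, nd_policy, detection_limits)
        for a in set(sample.conc) | set(sample.nondetect)
    )


def carcinogenic_sum(
    sample: WaterSample,
    pefs: Optional[PEFTable] = None,
    nd_policy: str = "zero",
    detection_limits: Optional[Mapping[str, float]] = None,
) -> float:
    """Unweighted sum over the carcinogenic subset (ng/L)."""
    _check_policy(nd_policy)
    pefs = pefs or PEFTable()
    return sum(
        _resolve(sample, a, nd_policy, detection_limits)
        for a in pefs.carcinogenic_set
        if sample.measured(a)
    )


def screen_sample(
    sample: WaterSample,
    standard: Standard,
    pefs: Optional[PEFTable] = None,
    nd_policy: str = "zero",
    detection_limits: Optional[Mapping[str, float]] = None,
) -> Dict[str, bool]:
    """Exceedance flags for one sample against a standard.

    Returns one boolean per defined limit, keyed ``<analyte>``, ``total``
    and ``bapeq``.  A flag is True iff the quantity strictly exceeds the
    limit.
    """
    pefs = pefs or PEFTable()
    flags: Dict[str, bool] = {}
    for analyte, limit in standard.analyte_limits.items():
        value = _resolve(sample, analyte, nd_policy, detection_limits)
        flags[analyte] = value > limit
    if standard.total_limit is not None:
        flags["total"] = total_pahs(sample, nd_policy, detection_limits) > standard.total_limit
    if standard.bapeq_limit is not None:
        flags["bapeq"] = (
            bapeq_concentration(sample, pefs, nd_policy, detection_limits)
            > standard.bapeq_limit
        )
    return flags
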