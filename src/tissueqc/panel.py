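"""Marker-gene panel for biological quality control of tissue libraries.

A small panel (neuron marker, glia marker, driver transgene,
contaminant-tissue marker, ubiquitous control) flags libraries whose
expression pattern does not match the target tissue: a library is
*contaminated* when every contaminant marker is elevated above its
ceiling AND some target-tissue marker falls below its floor; a
non-contaminated library with weak transgene expression is flagged
*low_transgene* separately (driver activity, not tissue identity).
The contamination score log2[(1 + mean contaminant FPKM) /
(1 + mean target-marker FPKM)] orders libraries by severity.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import CountMatrix

TARGET_ROLES = ("target_tissue_neuron", "target_tissue_glia")
ROLES = TARGET_ROLES + ("transgene", "contaminant", "ubiquitous_control")

#: Floor for target-tissue markers, as a fraction of their target-tissue
#: reference FPKM. Contamination dilutes a target marker to (1-c) of its
#: reference, so the floor sits close to the reference and specificity is
#: carried by the contaminant-marker ceiling (a contaminant marker must
#: rise far above its target-tissue level before a library can be
#: flagged at all).
DEFAULT_TARGET_MIN_FRACTION = 0.95
#: Ceiling for contaminant markers, as a multiple of their target-tissue
#: reference FPKM. A strongly tissue-enriched marker rises an order of
#: magnitude above its target-tissue level at moderate contamination, so
#: the ceiling sits several noise standard deviations above the clean
#: mean without costing sensitivity.
DEFAULT_CONTAMINANT_MAX_FRACTION = 3.0
#: Transgene floor: fraction of the median transgene FPKM across
#: reference-conformant (non-contaminated) libraries. A library must
#: sit far (4x) below its peers before driver activity is called low:
#: at biological NB dispersion ~0.1 the per-library FPKM CV is ~30%,
#: so a floor near the median would routinely misfire on replicates
#: with normal driver activity.
DEFAULT_TRANSGENE_MIN_FRACTION = 0.25


@dataclass
class MarkerEntry:
    gene_id: str
    role: str
    ref_fpkm_target: float  # reference FPKM in the target tissue
    ref_fpkm_contaminant: float  # reference FPKM in the contaminant tissue
    min_fpkm: float | None = None
    max_fpkm: float | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown marker role {self.role!r}")
        for thr in (self.min_fpkm, self.max_fpkm):
            if thr is not None and thr <= 0:
                raise ValueError("thresholds must be positive where set")


@dataclass
class MarkerPanel:
    entries: list[MarkerEntry]
    target_min_fraction: float = DEFAULT_TARGET_MIN_FRACTION
    contaminant_max_fraction: float = DEFAULT_CONTAMINANT_MAX_FRACTION
    transgene_min_fraction: float = DEFAULT_TRANSGENE_MIN_FRACTION

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("empty marker panel")
        roles = [e.role for e in self.entries]
        if not any(r in TARGET_ROLES for r in roles):
            raise ValueError("panel needs >= 1 target-tissue marker")
        if "contaminant" not in roles:
            raise ValueError("panel needs >= 1 contaminant marker")
        if roles.count("transgene") != 1:
            raise ValueError("panel needs exactly 1 transgene entry")

    def by_role(self, *roles: str) -> list[MarkerEntry]:
        return [e for e in self.entries if e.role in roles]

    @property
    def transgene(self) -> MarkerEntry:
        return self.by_role("transgene")[0]

    def with_default_thresholds(self) -> "MarkerPanel":
        """Fill unset thresholds from the relative-to-reference defaults.

        The transgene floor depends on the evaluated libraries and is
        resolved at evaluation time when left unset.
        """
        entries = []
        for e in self.entries:
            if e.role in TARGET_ROLES and e.min_fpkm is None:
                e = replace(e, min_fpkm=self.target_min_fraction * e.ref_fpkm_target)
            elif e.role == "contaminant" and e.max_fpkm is None:
                e = replace(
                    e, max_fpkm=self.contaminant_max_fraction * e.ref_fpkm_target
                )
            entries.append(e)
        return replace(self, entries=entries)


@dataclass
class LibraryVerdict:
    library: str
    contaminated: bool
    low_transgene: bool
    score: float  # contamination score, larger = worse
    marker_fpkm: dict = field(default_factory=dict)
    comparisons: list = field(default_factory=list)  # (gene, kind, fpkm, threshold, failed)

    @property
    def passed(self) -> bool:
        return not (self.contaminated or self.low_transgene)


def _marker_fpkm(fpkm_matrix: pd.DataFrame, entry: MarkerEntry, library: str) -> float:
    if entry.gene_id in fpkm_matrix.index:
        return float(fpkm_matrix.at[entry.gene_id, library])
    if entry.role == "transgene":
        return 0.0  # quantified against its own reference: absence means zero
    raise ValueError(f"panel gene {entry.gene_id} missing from FPKM matrix")


def contamination_score(
    contaminant_fpkm: np.ndarray | list, target_fpkm: np.ndarray | list
) -> float:
    return float(
        np.log2((1.0 + np.mean(contaminant_fpkm)) / (1.0 + np.mean(target_fpkm)))
    )


def evaluate_panel(
    fpkm_matrix: pd.DataFrame, panel: MarkerPanel
) -> dict[str, LibraryVerdict]:
    """Score every library of an FPKM matrix against the marker panel."""
    panel = panel.with_default_thresholds()
    targets = panel.by_role(*TARGET_ROLES)
    contaminants = panel.by_role("contaminant")
    transgene = panel.transgene

    verdicts: dict[str, LibraryVerdict] = {}
    for lib in fpkm_matrix.columns:
        obs = {e.gene_id: _marker_fpkm(fpkm_matrix, e, lib) for e in panel.entries}
        comparisons = []
        high_contaminant = True
        for e in contaminants:
            failed = obs[e.gene_id] > e.max_fpkm
            comparisons.append((e.gene_id, "max", obs[e.gene_id], e.max_fpkm, failed))
            high_contaminant &= failed
        low_target = False
        for e in targets:
            failed = obs[e.gene_id] < e.min_fpkm
            comparisons.append((e.gene_id, "min", obs[e.gene_id], e.min_fpkm, failed))
            low_target |= failed
        contaminated = high_contaminant and low_target
        score = contamination_score(
            [obs[e.gene_id] for e in contaminants],
            [obs[e.gene_id] for e in targets],
        )
        verdicts[lib] = LibraryVerdict(lib, contaminated, False, score, obs, comparisons)

    # transgene floor: relative to reference-conformant libraries
    tg_min = transgene.min_fpkm
    if tg_min is None:
        conformant = [v for v in verdicts.values() if not v.contaminated]
        pool = conformant or list(verdicts.values())
        tg_min = panel.transgene_min_fraction * float(
            np.median([v.marker_fpkm[transgene.gene_id] for v in pool])
        )
    for v in verdicts.values():
        tg_obs = v.marker_fpkm[transgene.gene_id]
        failed = (not v.contaminated) and tg_obs < tg_min
        v.comparisons.append((transgene.gene_id, "min", tg_obs, tg_min, failed))
        v.low_transgene = failed
    return verdicts


def verdicts_frame(verdicts: dict[str, LibraryVerdict]) -> pd.DataFrame:
    rows = []
    for v in verdicts.values():
        row = {
            "library": v.library,
            "contaminated": v.contaminated,
            "low_transgene": v.low_transgene,
            "pass": v.passed,
            "score": v.score,
        }
        row.update({f"fpkm_{g}": x for g, x in v.marker_fpkm.items()})
        rows.append(row)
    return pd.DataFrame(rows).set_index("library")


def estimate_contamination(
    observed_fpkm: float | pd.Series, entry: MarkerEntry
) -> float | pd.Series:
    """Contaminant-tissue fraction from the linear mixing of a marker:
    c = (observed - ref_target) / (ref_contaminant - ref_target),
    clamped to [0, 1]."""
    if entry.ref_fpkm_contaminant <= entry.ref_fpkm_target:
        raise ValueError(
            "contaminant-tissue reference must exceed target-tissue reference"
        )
    c = (observed_fpkm - entry.ref_fpkm_target) / (
        entry.ref_fpkm_contaminant - entry.ref_fpkm_target
    )
    return np.clip(c, 0.0, 1.0)


def select_libraries(
    verdicts: dict[str, LibraryVerdict],
    counts: CountMatrix,
    min_per_group: int = 2,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Keep passing libraries; log exclusions; refuse depleted groups."""
    keep, excluded = [], []
    for lib in counts.libraries:
        v = verdicts.get(lib)
        if v is None:
            raise ValueError(f"no verdict for library {lib}")
        if v.passed:
            keep.append(lib)
        else:
            flag = "contaminated" if v.contaminated else "low_transgene"
            excluded.append({"library": lib, "flag": flag, "score": v.score})
    if not counts.meta.empty:
        remaining = counts.meta.loc[keep, "group"].value_counts()
        for group in counts.meta["group"].unique():
            if remaining.get(group, 0) < min_per_group:
                raise ValueError(
                    f"group {group!r} left with "
                    f"{int(remaining.get(group, 0))} passing libraries "
                    f"(< {min_per_group})"
                )
    log = pd.DataFrame(excluded, columns=["library", "flag", "score"])
    return counts.subset(keep), log


def reference_panel_from_profiles(
    profiles, genes, phi: float, library_size: float = 1e6
) -> MarkerPanel:
    """Expected-FPKM reference panel from simulator tissue profiles.

    Reference FPKMs are the noise-free FPKM of each marker in the pure
    target-tissue mixture (c=0, no knockdown) and in the pure
    contaminant tissue (c=1).
    """
    from .sim import mixture_abundance  # local import to avoid a cycle

    lengths = {g.gene_id: g.union_length for g in genes}
    a_target = mixture_abundance(profiles, phi, 0.0, 1.0)
    a_contam = profiles.contaminant
    role_map = {
        "neuron_marker": "target_tissue_neuron",
        "glia_marker": "target_tissue_glia",
        "contaminant_marker": "contaminant",
        "ubiquitous_control": "ubiquitous_control",
        "transgene": "transgene",
    }

    def expected_fpkm(abund: np.ndarray, gid: str) -> float:
        idx = profiles.index()[gid]
        share = abund[idx] / abund.sum()
        return 1e9 * share / lengths[gid]  # counts/(kb * M) at any depth

    entries = []
    for sim_role, panel_role in role_map.items():
        gid = profiles.roles[sim_role]
        entries.append(
            MarkerEntry(
                gene_id=gid,
                role=panel_role,
                ref_fpkm_target=expected_fpkm(a_target, gid),
                ref_fpkm_contaminant=expected_fpkm(a_contam, gid),
            )
        )
    return MarkerPanel(entries)
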