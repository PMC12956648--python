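"""Wild-type-referenced electronic perturbation descriptors.

Given parsed per-atom charges (NPA or CHELPG) and orbital spectra for a
mutant cohort plus the wild-type fragment, this module computes the
comparative descriptors: summed fragment charges, atom-aligned charge
matrices, Δq vectors relative to wild type with their L1 norms, HOMO–LUMO
gap tables, and a PCA of the charge matrix.

Fragments of different mutants can have different atom counts (nonsense
windows are shorter, side chains differ), so cross-mutant alignment is
index-wise on the canonical atom ordering (residue order, then file order
within a residue): rows are padded with NaN beyond a fragment's atom count
and Δq is truncated to the common prefix, whose length is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AggregationError, MethodMismatchError, RankError
from .qchem_io import HARTREE_TO_EV, ChargeSet, OrbitalSpectrum

__all__ = [
    "PerturbationProfile",
    "PCAResult",
    "summed_charge",
    "align_charge_matrix",
    "delta_vs_wt",
    "l1_perturbation",
    "gap_table",
    "pca_scores",
    "perturbation_summary",
]


def summed_charge(cs: ChargeSet) -> float:
    """Total fragment charge: the sum of per-atom partial charges."""
    if cs.n_atoms == 0:
        raise AggregationError("cannot sum an empty charge set")
    return float(cs.as_array().sum())


def align_charge_matrix(sets: dict[str, ChargeSet]) -> pd.DataFrame:
    """Stack per-mutant charge vectors into a mutants × atom-index matrix.

    Columns are 1-based atom indices up to the largest fragment; shorter rows
    are NaN-padded. All sets must share one population method; it is recorded
    in ``DataFrame.attrs["method"]``.
    """
    if not sets:
        raise AggregationError("no charge sets to align")
    methods = {cs.method for cs in sets.values()}
    if len(methods) > 1:
        raise MethodMismatchError(f"mixed charge methods: {sorted(methods)}")
    width = max(cs.n_atoms for cs in sets.values())
    data = np.full((len(sets), width), np.nan)
    ids = list(sets)
    for i, mutant in enumerate(ids):
        q = sets[mutant].as_array()
        data[i, : q.size] = q
    df = pd.DataFrame(data, index=ids, columns=range(1, width + 1))
    df.attrs["method"] = methods.pop()
    return df


@dataclass(frozen=True)
class PerturbationProfile:
    """Charge perturbation of one mutant relative to the wild-type fragment."""

    mutant_id: str
    delta: tuple[float, ...]
    l1: float
    n_common: int
    gap: float | None = None

    def delta_array(self) -> np.ndarray:
        return np.asarray(self.delta, dtype=float)


def delta_vs_wt(
    mut: ChargeSet, wt: ChargeSet, mutant_id: str = "",
    spectrum: OrbitalSpectrum | None = None,
) -> PerturbationProfile:
    """Δq_i = q_i(mut) − q_i(WT) over the common atom-index prefix."""
    if mut.method != wt.method:
        raise MethodMismatchError(
            f"cannot compare {mut.method} against {wt.method} charges"
        )
    n_common = min(mut.n_atoms, wt.n_atoms)
    delta = mut.as_array()[:n_common] - wt.as_array()[:n_common]
    return PerturbationProfile(
        mutant_id=mutant_id,
        delta=tuple(float(d) for d in delta),
        l1=l1_perturbation(delta),
        n_common=n_common,
        gap=spectrum.gap if spectrum is not None else None,
    )


def l1_perturbation(delta) -> float:
    """Magnitude of a charge perturbation: Σ|Δq_i|."""
    return float(np.abs(np.asarray(delta, dtype=float)).sum())


def gap_table(spectra: dict[str, OrbitalSpectrum]) -> pd.DataFrame:
    """One row per mutant (id-sorted): E_HOMO, E_LUMO, gap (hartree), gap_ev.

    The gap is recomputed from the energies, never taken on trust from the
    output text.
    """
    rows = []
    for mutant in sorted(spectra):
        s = spectra[mutant]
        gap = s.e_lumo - s.e_homo
        rows.append(
            {
                "mutant": mutant,
                "e_homo": s.e_homo,
                "e_lumo": s.e_lumo,
                "gap": gap,
                "gap_ev": gap * HARTREE_TO_EV,
            }
        )
    return pd.DataFrame(rows, columns=["mutant", "e_homo", "e_lumo", "gap", "gap_ev"])


@dataclass(frozen=True)
class PCAResult:
    """Principal-component scores of the (imputed, centred) charge matrix."""

    scores: pd.DataFrame  # mutants × components
    explained: tuple[float, ...]  # variance fractions, descending
    components: np.ndarray  # k × atoms loadings


def pca_scores(matrix: pd.DataFrame, k: int = 2) -> PCAResult:
    """PCA of the charge matrix via column-centred SVD.

    Missing cells are imputed to their column mean first. Sign convention:
    each component is flipped so its largest-|loading| entry is positive,
    making scores deterministic. ``k`` may not exceed the matrix rank;
    ``k=0`` returns empty scores.
    """
    if matrix.shape[0] < 2:
        raise RankError("PCA needs at least 2 rows")
    X = matrix.to_numpy(dtype=float)
    col_mean = np.nanmean(X, axis=0)
    nan_rows, nan_cols = np.nonzero(np.isnan(X))
    X[nan_rows, nan_cols] = col_mean[nan_cols]
    X = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    tol = S.max(initial=0.0) * max(X.shape) * np.finfo(float).eps
    rank = int((S > tol).sum())
    if k > rank:
        raise RankError(f"k={k} exceeds matrix rank {rank}")
    total_var = float((S**2).sum())
    explained = tuple((S[:k] ** 2 / total_var).tolist()) if total_var > 0 else ()
    # deterministic sign: dominant loading of each kept component positive
    for j in range(k):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = pd.DataFrame(
        U[:, :k] * S[:k],
        index=matrix.index,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return PCAResult(scores=scores, explained=explained, components=Vt[:k].copy())


def perturbation_summary(
    charge_sets: dict[str, ChargeSet],
    spectra: dict[str, OrbitalSpectrum],
    wt_id: str,
) -> pd.DataFrame:
    """Per-mutant descriptor table: summed charge, L1 vs WT, HOMO/LUMO/gap.

    The wild type is included as its own zero-perturbation reference row.
    """
    if wt_id not in charge_sets:
        raise AggregationError(f"wild-type id {wt_id!r} missing from charge sets")
    wt = charge_sets[wt_id]
    rows = []
    for mutant in sorted(charge_sets):
        cs = charge_sets[mutant]
        profile = delta_vs_wt(cs, wt, mutant, spectra.get(mutant))
        s = spectra.get(mutant)
        rows.append(
            {
                "mutant": mutant,
                "summed_charge": summed_charge(cs),
                "l1_vs_wt": profile.l1,
                "n_common": profile.n_common,
                "e_homo": s.e_homo if s else np.nan,
                "e_lumo": s.e_lumo if s else np.nan,
                "gap_ev": s.gap_ev if s else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("mutant")
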