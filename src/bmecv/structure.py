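"""Secondary-structure-derived quantities.

Per-residue helical content under arbitrary frame weights, random-coil
reference shifts averaged over coil conformations, and secondary shifts
(observable minus coil reference).

The coil reference is computed per residue POSITION by default, with an
optional pooled mode (one value per atom kind).  It always uses the prior
(typically uniform) weights, never reweighted ones, so the observable map
stays fixed across a theta scan.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .ensemble import (
    AtomKind,
    ObservableMatrix,
    SSMatrix,
    TargetSet,
    WeightVector,
    uniform_weights,
)
from .errors import ValidationError

__all__ = [
    "CoilReference",
    "helical_fraction",
    "coil_reference",
    "secondary_shifts",
    "secondary_target_set",
]


@dataclass
class CoilReference:
    """Random-coil reference shifts per (residue position, atom kind).

    ``ref`` maps (residue_index, atom_kind) to the reference value;
    ``coverage`` counts the frames that contributed.  Cells with zero
    coverage carry the atom-kind global coil mean as fallback.
    """

    ref: dict
    coverage: dict
    atom_fallback: dict
    pooled: bool = False

    def lookup(self, residue_index: int, atom_kind: AtomKind) -> float:
        key = (residue_index, atom_kind)
        if key in self.ref and self.coverage.get(key, 0) > 0:
            return self.ref[key]
        if atom_kind in self.atom_fallback:
            return self.atom_fallback[atom_kind]
        raise ValidationError(
            f"no coil reference available for residue {residue_index} atom {atom_kind.value}"
        )

    def to_tsv(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("residue\tatom\treference\tcoverage\n")
            for (res, atom), val in sorted(
                self.ref.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
            ):
                fh.write(
                    f"{res}\t{atom.value}\t{'%.17g' % val}\t{self.coverage[(res, atom)]}\n"
                )


def helical_fraction(ss: SSMatrix, w: WeightVector) -> np.ndarray:
    """Weighted fraction of frames in helix per residue, in [0, 1]."""
    if len(w) != ss.n_frames:
        raise ValidationError(
            f"weight length {len(w)} does not match {ss.n_frames} frames"
        )
    return w.weights @ (ss.codes == "H").astype(float)


def _resolved_labels(cs: ObservableMatrix) -> list[tuple[int, AtomKind]]:
    out = []
    for lab in cs.labels:
        if lab.residue_index is None:
            raise ValidationError(
                f"label {lab.tag!r} has no residue metadata; cannot map onto the sequence"
            )
        out.append((lab.residue_index, lab.atom_kind))
    return out


def coil_reference(
    cs: ObservableMatrix,
    ss: SSMatrix,
    w0: WeightVector | None = None,
    pool_residues: bool = False,
) -> CoilReference:
    """Weighted mean observable over coil-assigned frames, per (residue, atom).

    ``pool_residues=True`` collapses the reference to one value per atom
    kind (the global coil mean).  An atom kind with no coil occurrence
    anywhere is an error; an individual residue that is never coil falls
    back to the atom-kind global mean with coverage 0.
    """
    if w0 is None:
        w0 = uniform_weights(cs.n_frames)
    if len(w0) != cs.n_frames or ss.n_frames != cs.n_frames:
        raise ValidationError("cs, ss and w0 must agree on the number of frames")
    keys = _resolved_labels(cs)
    for res, _ in keys:
        if res > ss.n_residues:
            raise ValidationError(
                f"label residue {res} outside secondary-structure matrix (R={ss.n_residues})"
            )

    is_coil = ss.codes == "C"
    ref: dict = {}
    coverage: dict = {}
    pooled_num: dict = {}
    pooled_den: dict = {}
    pooled_cov: dict = {}
    for j, (res, atom) in enumerate(keys):
        mask = is_coil[:, res - 1]
        cov = int(mask.sum())
        wsum = float(w0.weights[mask].sum())
        coverage[(res, atom)] = cov
        if cov > 0 and wsum > 0:
            ref[(res, atom)] = float(
                np.sum(w0.weights[mask] * cs.values[mask, j]) / wsum
            )
        pooled_num[atom] = pooled_num.get(atom, 0.0) + float(
            np.sum(w0.weights[mask] * cs.values[mask, j])
        )
        pooled_den[atom] = pooled_den.get(atom, 0.0) + wsum
        pooled_cov[atom] = pooled_cov.get(atom, 0) + cov

    atom_fallback: dict = {}
    for atom in pooled_num:
        if pooled_cov[atom] == 0 or pooled_den[atom] <= 0:
            raise ValidationError(
                f"atom kind {atom.value} has no coil-assigned frames anywhere"
            )
        atom_fallback[atom] = pooled_num[atom] / pooled_den[atom]

    if pool_residues:
        ref = {key: atom_fallback[key[1]] for key in coverage}
    return CoilReference(
        ref=ref, coverage=coverage, atom_fallback=atom_fallback, pooled=pool_residues
    )


def secondary_shifts(cs: ObservableMatrix, ref: CoilReference) -> ObservableMatrix:
    """Subtract the coil reference from every observable column."""
    offsets = np.array(
        [ref.lookup(res, atom) for res, atom in _resolved_labels(cs)]
    )
    return replace(
        cs,
        values=cs.values - offsets,
        labels=list(cs.labels),
        frame_ids=list(cs.frame_ids),
    )


def secondary_target_set(
    target_cs: TargetSet,
    target_ensemble_cs: ObservableMatrix,
    target_ss: SSMatrix,
    pool_residues: bool = False,
) -> TargetSet:
    """Convert target values to secondary shifts using the TARGET ensemble's
    own coil reference (uniform weights); sigmas are unchanged."""
    if target_cs.tags != target_ensemble_cs.tags:
        raise ValidationError("target set and target ensemble must share tags")
    ref = coil_reference(
        target_ensemble_cs, target_ss, pool_residues=pool_residues
    )
    offsets = np.array(
        [
            ref.lookup(lab.residue_index, lab.atom_kind)
            if lab.residue_index is not None
            else _raise_unresolved(lab.tag)
            for lab in target_cs.labels
        ]
    )
    return TargetSet(
        labels=list(target_cs.labels),
        values=target_cs.values - offsets,
        sigmas=target_cs.sigmas.copy(),
    )


def _raise_unresolved(tag: str):
    raise ValidationError(f"label {tag!r} has no residue metadata")
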