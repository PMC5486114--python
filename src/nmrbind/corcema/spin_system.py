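"""Labelled proton spin systems for the relaxation-matrix simulator."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["SpinSystem"]

# residues carrying methyl groups and the names of their methyl hydrogens
_METHYL_H_NAMES = {
    "ALA": ("HB1", "HB2", "HB3"),
    "VAL": ("HG11", "HG12", "HG13", "HG21", "HG22", "HG23"),
    "LEU": ("HD11", "HD12", "HD13", "HD21", "HD22", "HD23"),
    "ILE": ("HG21", "HG22", "HG23", "HD11", "HD12", "HD13"),
    "THR": ("HG21", "HG22", "HG23"),
    "MET": ("HE1", "HE2", "HE3"),
}


@dataclass
class SpinSystem:
    """Proton coordinates and roles for a ligand-protein complex.

    ``coords_bound`` holds one xyz row (Angstrom) per proton in the bound
    complex; ligand rows of ``coords_free`` give the free-ligand geometry
    (defaults to the bound ligand geometry).  ``methyl_ids`` groups protons
    sharing a methyl carbon (-1 = not a methyl proton); ``saturated`` marks
    the protein protons irradiated on-resonance.
    """

    labels: list[str]
    owners: list[str]  # "ligand" | "protein" per proton
    coords_bound: np.ndarray
    coords_free: np.ndarray | None = None
    methyl_ids: np.ndarray | None = None
    saturated: np.ndarray | None = None  # bool mask over all protons

    def __post_init__(self) -> None:
        n = len(self.labels)
        self.coords_bound = np.asarray(self.coords_bound, dtype=float)
        if self.coords_bound.shape != (n, 3):
            raise ValueError("coords_bound must be (n_protons, 3)")
        if not np.all(np.isfinite(self.coords_bound)):
            raise ValueError("coordinates must be finite")
        if len(self.owners) != n:
            raise ValueError("owners must match labels in length")
        bad = set(self.owners) - {"ligand", "protein"}
        if bad:
            raise ValueError(f"unknown owners: {sorted(bad)}")
        if self.methyl_ids is None:
            self.methyl_ids = np.full(n, -1, dtype=int)
        else:
            self.methyl_ids = np.asarray(self.methyl_ids, dtype=int)
            if self.methyl_ids.shape != (n,):
                raise ValueError("methyl_ids must have one entry per proton")
        if self.saturated is None:
            self.saturated = np.zeros(n, dtype=bool)
        else:
            self.saturated = np.asarray(self.saturated, dtype=bool)
            if self.saturated.shape != (n,):
                raise ValueError("saturated mask must have one entry per proton")
        if np.any(self.saturated & ~self.is_protein):
            raise ValueError("saturated set must be a subset of protein protons")
        if self.coords_free is not None:
            cf = np.asarray(self.coords_free, dtype=float)
            if cf.shape != (int(self.is_ligand.sum()), 3):
                raise ValueError("coords_free must be (n_ligand_protons, 3)")
            self.coords_free = cf

    @property
    def is_ligand(self) -> np.ndarray:
        return np.array([o == "ligand" for o in self.owners])

    @property
    def is_protein(self) -> np.ndarray:
        return ~self.is_ligand

    @property
    def ligand_labels(self) -> list[str]:
        return [l for l, o in zip(self.labels, self.owners) if o == "ligand"]

    @property
    def n_protons(self) -> int:
        return len(self.labels)

    def free_ligand_coords(self) -> np.ndarray:
        if self.coords_free is not None:
            return self.coords_free
        return self.coords_bound[self.is_ligand]

    def saturate(self, labels: list[str] | None = None) -> "SpinSystem":
        """Return a copy with the saturated set replaced.

        ``labels=None`` saturates every protein proton.
        """
        if labels is None:
            mask = self.is_protein.copy()
        else:
            unknown = set(labels) - set(self.labels)
            if unknown:
                raise ValueError(f"unknown proton labels: {sorted(unknown)}")
            mask = np.array([l in set(labels) for l in self.labels])
        return SpinSystem(
            labels=list(self.labels),
            owners=list(self.owners),
            coords_bound=self.coords_bound.copy(),
            coords_free=None if self.coords_free is None else self.coords_free.copy(),
            methyl_ids=self.methyl_ids.copy(),
            saturated=mask,
        )

    # ------------------------------------------------------------------ I/O

    def to_json(self, path: str | Path) -> None:
        records = [
            {
                "label": lab,
                "owner": own,
                "xyz": [float(v) for v in xyz],
                "methyl_id": int(mid),
                "saturated": bool(sat),
            }
            for lab, own, xyz, mid, sat in zip(
                self.labels, self.owners, self.coords_bound, self.methyl_ids,
                self.saturated,
            )
        ]
        payload: dict = {"protons": records}
        if self.coords_free is not None:
            payload["free_ligand_xyz"] = self.coords_free.tolist()
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SpinSystem":
        payload = json.loads(Path(path).read_text())
        protons = payload["protons"]
        coords_free = payload.get("free_ligand_xyz")
        return cls(
            labels=[p["label"] for p in protons],
            owners=[p["owner"] for p in protons],
            coords_bound=np.array([p["xyz"] for p in protons], dtype=float),
            coords_free=None if coords_free is None else np.asarray(coords_free),
            methyl_ids=np.array([p.get("methyl_id", -1) for p in protons]),
            saturated=np.array([p.get("saturated", False) for p in protons]),
        )

    @classmethod
    def from_pdb(
        cls,
        path: str | Path,
        ligand_resnames: set[str] | None = None,
        saturate_methyls: bool = True,
    ) -> "SpinSystem":
        """Build a spin system from a protonated PDB of the complex.

        Hetero (non-polymer, non-water) residues are taken as the ligand
        unless ``ligand_resnames`` pins them explicitly.  Files without
        explicit hydrogens are rejected: protonate upstream (e.g. reduce,
        pdb2pqr, OpenBabel) and re-run.  By default all protein methyl
        protons are marked saturated, matching on-resonance irradiation of
        the methyl region.
        """
        import biotite.structure as struc
        from biotite.structure.io.pdb import PDBFile

        atoms = PDBFile.read(str(path)).get_structure(model=1)
        atoms = atoms[atoms.res_name != "HOH"]
        is_h = atoms.element == "H"
        if not np.any(is_h):
            raise ValueError(
                f"{path} contains no explicit hydrogens; protonate the "
                "structure upstream and retry"
            )
        if ligand_resnames is not None:
            lig_mask = np.isin(atoms.res_name, sorted(ligand_resnames))
        else:
            lig_mask = atoms.hetero
        if not np.any(lig_mask & is_h):
            raise ValueError("no ligand hydrogens found in the structure")

        h = atoms[is_h]
        h_lig = lig_mask[is_h]
        labels, owners, methyl_ids, saturated = [], [], [], []
        methyl_key_to_id: dict[tuple, int] = {}
        for i in range(h.array_length()):
            owner = "ligand" if h_lig[i] else "protein"
            owners.append(owner)
            labels.append(
                f"{h.chain_id[i]}:{h.res_name[i]}{h.res_id[i]}:{h.atom_name[i]}"
            )
            res, name = h.res_name[i], h.atom_name[i]
            is_methyl = owner == "protein" and name in _METHYL_H_NAMES.get(res, ())
            if is_methyl:
                # protons of one methyl share the parent carbon name (strip
                # the trailing branch digit of the hydrogen name)
                key = (h.chain_id[i], int(h.res_id[i]), name[:-1])
                mid = methyl_key_to_id.setdefault(key, len(methyl_key_to_id))
            else:
                mid = -1
            methyl_ids.append(mid)
            saturated.append(is_methyl and saturate_methyls)
        return cls(
            labels=labels,
            owners=owners,
            coords_bound=h.coord.astype(float),
            methyl_ids=np.array(methyl_ids),
            saturated=np.array(saturated),
        )
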