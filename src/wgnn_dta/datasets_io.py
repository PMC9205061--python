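"""Pair-table datasets: loading, the Davis-style affinity transform, and
a fully synthetic fixture generator with a planted, learnable signal.

A dataset is a table of (molecule, protein, label) records plus the
side information needed to featurize both partners: a residue sequence
and a contact map per protein.  Labels are continuous affinities (e.g.
pKd) for the regression task or {0, 1} for binary interaction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from rdkit import Chem

from .contact_maps import (
    ContactMap,
    load_contact_map,
    merge_contact_maps,
    plan_windows,
    save_contact_map,
    split_contact_map,
    synth_contact_map,
)

__all__ = [
    "PairRecord",
    "PairDataset",
    "SyntheticSignal",
    "load_pair_table",
    "save_pair_table",
    "apply_davis_transform",
    "generate_synthetic_dataset",
    "AROMATIC_RESIDUES",
]

AROMATIC_RESIDUES = set("FWY")


@dataclass(frozen=True)
class PairRecord:
    mol_id: str
    smiles: str
    prot_id: str
    label: float


@dataclass
class PairDataset:
    """Aligned molecule-protein pair records with per-protein sequences
    and contact maps.  ``task`` is ``"dta"`` (continuous label) or
    ``"cpi"`` (binary label)."""

    records: list[PairRecord]
    sequences: dict[str, str]
    contact_maps: Mapping[str, ContactMap]
    task: str = "dta"

    def __post_init__(self) -> None:
        if self.task not in ("dta", "cpi"):
            raise ValueError(f"task must be 'dta' or 'cpi', got {self.task!r}")
        self.validate()

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records])

    def validate(self) -> None:
        missing_seq = sorted(
            {r.prot_id for r in self.records} - set(self.sequences)
        )
        if missing_seq:
            raise KeyError(f"proteins without a sequence: {missing_seq}")
        missing_map = sorted(
            {r.prot_id for r in self.records} - set(self.contact_maps)
        )
        if missing_map:
            raise KeyError(f"proteins without a contact map: {missing_map}")
        for pid, seq in self.sequences.items():
            cmap = self.contact_maps.get(pid)
            if cmap is not None and cmap.length != len(seq):
                raise ValueError(
                    f"protein {pid}: sequence length {len(seq)} vs contact "
                    f"map side {cmap.length}"
                )
        for row, rec in enumerate(self.records):
            if not rec.mol_id or not rec.prot_id:
                raise ValueError(f"row {row}: empty molecule or protein id")
            if Chem.MolFromSmiles(rec.smiles) is None:
                raise ValueError(
                    f"row {row}: unparseable SMILES {rec.smiles!r}"
                )
            if self.task == "cpi" and rec.label not in (0.0, 1.0):
                raise ValueError(
                    f"row {row}: CPI label must be 0 or 1, got {rec.label}"
                )

    def subset(self, indices) -> "PairDataset":
        recs = [self.records[i] for i in np.asarray(indices, dtype=int)]
        return PairDataset(
            records=recs,
            sequences=self.sequences,
            contact_maps=self.contact_maps,
            task=self.task,
        )


def load_pair_table(
    csv_path: str | Path,
    fasta_path: str | Path,
    contact_dir: str | Path,
    task: str = "dta",
    dialect: str = "matrix-text",
) -> PairDataset:
    """Load a pair table (CSV with columns mol_id, smiles, prot_id, label),
    sequences (FASTA keyed by prot_id) and contact maps (one file per
    protein in ``contact_dir``, named ``<prot_id>.txt`` for the text
    dialect or ``<prot_id>.npy`` for the binary one).  Row order is
    preserved; duplicate (mol_id, prot_id) rows are legal and kept.
    """
    df = pd.read_csv(csv_path, float_precision="round_trip")
    required = ["mol_id", "smiles", "prot_id", "label"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{csv_path}: missing columns {missing_cols}")
    sequences = {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    contact_dir = Path(contact_dir)
    ext = ".txt" if dialect == "matrix-text" else ".npy"
    prot_ids = df["prot_id"].astype(str).unique()
    missing = [
        pid for pid in prot_ids if not (contact_dir / f"{pid}{ext}").exists()
    ]
    if missing:
        raise KeyError(f"no contact-map file for proteins: {sorted(missing)}")
    contact_maps = {
        pid: load_contact_map(contact_dir / f"{pid}{ext}", dialect=dialect)
        for pid in prot_ids
    }
    records = [
        PairRecord(str(r.mol_id), str(r.smiles), str(r.prot_id), float(r.label))
        for r in df.itertuples(index=False)
    ]
    return PairDataset(records, sequences, contact_maps, task=task)


def save_pair_table(
    dataset: PairDataset,
    csv_path: str | Path,
    fasta_path: str | Path,
    contact_dir: str | Path,
    dialect: str = "matrix-text",
) -> None:
    """Write a dataset back out in the on-disk layout load_pair_table reads."""
    pd.DataFrame(
        [(r.mol_id, r.smiles, r.prot_id, repr(r.label)) for r in dataset.records],
        columns=["mol_id", "smiles", "prot_id", "label"],
    ).to_csv(csv_path, index=False)
    with open(fasta_path, "w") as fh:
        for pid, seq in dataset.sequences.items():
            fh.write(f">{pid}\n{seq}\n")
    contact_dir = Path(contact_dir)
    contact_dir.mkdir(parents=True, exist_ok=True)
    ext = ".txt" if dialect == "matrix-text" else ".npy"
    for pid, cmap in dataset.contact_maps.items():
        save_contact_map(cmap, contact_dir / f"{pid}{ext}", dialect=dialect)


def apply_davis_transform(dataset: PairDataset) -> PairDataset:
    """Replace nanomolar Kd labels by pKd = -log10(Kd / 1e9)."""
    from .train_eval import pkd_transform

    records = []
    for row, rec in enumerate(dataset.records):
        if rec.label <= 0:
            raise ValueError(
                f"row {row} ({rec.mol_id}, {rec.prot_id}): Kd must be "
                f"positive, got {rec.label}"
            )
        records.append(replace(rec, label=pkd_transform(rec.label)))
    return PairDataset(
        records, dataset.sequences, dataset.contact_maps, task=dataset.task
    )


# ---------------------------------------------------------------------------
# synthetic data
# ---------------------------------------------------------------------------

# chemically valid SMILES templates spanning aromatic fractions 0..1:
# linear/branched alkanes, alkylbenzenes and small fused/linked aromatics
def _molecule_pool() -> list[str]:
    linear = ["C" * n for n in range(2, 11)]
    branched = ["CC(C)C", "CC(C)(C)C", "CCC(C)CC", "CC(C)CC(C)C", "CCC(C)(C)CC"]
    alkylbenzenes = ["C" * k + "c1ccccc1" for k in range(0, 7)]
    others = [
        "Oc1ccccc1",  # phenol
        "Nc1ccccc1",  # aniline
        "c1ccc2ccccc2c1",  # naphthalene
        "c1ccc(-c2ccccc2)cc1",  # biphenyl
        "Cc1ccccc1C",  # o-xylene
    ]
    return linear + branched + alkylbenzenes + others


def _aromatic_atom_fraction(smiles: str) -> float:
    mol = Chem.MolFromSmiles(smiles)
    return sum(a.GetIsAromatic() for a in mol.GetAtoms()) / mol.GetNumAtoms()


def _aromatic_residue_fraction(seq: str) -> float:
    return sum(c in AROMATIC_RESIDUES for c in seq) / len(seq)


@dataclass(frozen=True)
class SyntheticSignal:
    """Ground truth planted by the generator.

    The noiseless score of a pair is
    ``w_protein * f_prot + w_molecule * f_mol`` where ``f_prot`` is the
    protein's aromatic-residue (F/W/Y) fraction and ``f_mol`` the
    molecule's aromatic-atom fraction; Gaussian noise of standard
    deviation ``sigma`` is added for regression labels, and
    classification labels threshold the noisy score at ``threshold``.
    """

    w_protein: float
    w_molecule: float
    sigma: float
    threshold: float | None
    protein_fraction: dict[str, float]
    molecule_fraction: dict[str, float]

    def noiseless_score(self, mol_id: str, prot_id: str) -> float:
        return (
            self.w_protein * self.protein_fraction[prot_id]
            + self.w_molecule * self.molecule_fraction[mol_id]
        )


def generate_synthetic_dataset(
    n_pairs: int,
    task: str = "dta",
    seed: int = 0,
    max_seq_len: int = 1200,
    n_proteins: int = 12,
    w_protein: float = 5.0,
    w_molecule: float = 5.0,
    noise_sigma: float = 0.3,
) -> tuple[PairDataset, SyntheticSignal]:
    """Generate a fully synthetic pair dataset with a planted signal.

    Proteins are random sequences over the 20 canonical residues; most
    are short (80-400 residues, typical single domains) and, when
    ``max_seq_len > 1000``, two are long (1001..max_seq_len) so their
    contact maps go through the window split/merge path, exactly as a
    length-limited predictor would produce them.  Contact maps come from
    the banded synthetic sampler.  Molecules are drawn from a fixed pool
    of valid alkane/aromatic SMILES whose aromatic-atom fraction spans
    [0, 1].  Labels carry the linear aromaticity signal described by
    :class:`SyntheticSignal`; for ``task="cpi"`` the noisy score is
    thresholded at the pool median of the noiseless score, giving roughly
    balanced classes.  Deterministic per seed.
    """
    if n_pairs < 2:
        raise ValueError(f"n_pairs must be >= 2, got {n_pairs}")
    rng = np.random.default_rng(seed)
    n_proteins = min(n_proteins, max(2, n_pairs // 2))

    # proteins
    alphabet = np.array(list("ARNDCQEGHILKMFPSTWYV"))
    n_long = 2 if (max_seq_len > 1000 and n_proteins >= 4) else 0
    lengths = list(rng.integers(80, 401, size=n_proteins - n_long))
    lengths += list(rng.integers(1001, max_seq_len + 1, size=n_long))
    sequences: dict[str, str] = {}
    contact_maps: dict[str, ContactMap] = {}
    for i, n_res in enumerate(map(int, lengths)):
        pid = f"P{i:03d}"
        sequences[pid] = "".join(rng.choice(alphabet, size=n_res))
        cmap = synth_contact_map(
            n_res, seed=int(rng.integers(2**31)), band_width=4,
            long_range_density=0.02,
        )
        if n_res > 1000:
            # emulate a length-limited predictor: per-window maps, merged
            plan = plan_windows(n_res)
            cmap = merge_contact_maps(split_contact_map(cmap, plan), plan, n_res)
        contact_maps[pid] = cmap

    # molecules
    pool = _molecule_pool()
    smiles_by_id = {f"M{i:03d}": smi for i, smi in enumerate(pool)}

    signal = SyntheticSignal(
        w_protein=w_protein,
        w_molecule=w_molecule,
        sigma=noise_sigma,
        threshold=None,
        protein_fraction={
            pid: _aromatic_residue_fraction(s) for pid, s in sequences.items()
        },
        molecule_fraction={
            mid: _aromatic_atom_fraction(s) for mid, s in smiles_by_id.items()
        },
    )

    prot_ids = list(sequences)
    mol_ids = list(smiles_by_id)
    pair_prots = [str(p) for p in rng.choice(prot_ids, size=n_pairs)]
    pair_mols = [str(m) for m in rng.choice(mol_ids, size=n_pairs)]
    scores = np.array(
        [signal.noiseless_score(m, p) for m, p in zip(pair_mols, pair_prots)]
    )
    noisy = scores + rng.normal(0.0, noise_sigma, size=n_pairs)

    if task == "cpi":
        all_scores = [
            signal.noiseless_score(m, p) for m in mol_ids for p in prot_ids
        ]
        threshold = float(np.median(all_scores))
        labels = (noisy > threshold).astype(float)
        signal = replace(signal, threshold=threshold)
    else:
        labels = noisy

    records = [
        PairRecord(m, smiles_by_id[m], p, float(y))
        for m, p, y in zip(pair_mols, pair_prots, labels)
    ]
    dataset = PairDataset(records, sequences, contact_maps, task=task)
    return dataset, signal
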