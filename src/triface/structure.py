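"""Trimer structure parsing, geometric features and interface labels.

Five per-residue geometric quantities feed the descriptor: solvent
accessible surface area of the residue inside the full complex
(``asa_bound``), its ratio to the ASA of the residue in its isolated
chain (``rasa``), the exterior contact area with atoms of the other two
chains (``eca``), the interior contact area with non-adjacent residues of
the same chain (``ica``), and the exterior void area
``eva = max(0, (asa_unbound - asa_bound) - eca)`` — the part of the
surface buried on binding that is not in direct atomic contact.

ASA is computed by Shrake–Rupley sphere sampling over probe-expanded van
der Waals spheres. The contact area of two atoms is the mean lateral
(spherical-cap) area of the lens where their probe-expanded spheres
overlap; two residues from different chains form an *interface residue
pair* exactly when their total atom-atom contact area is positive.
TSV importers let users inject per-residue ASA, per-pair contact areas,
or per-residue pKa values computed with external tools instead.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from scipy.spatial import cKDTree

from .scales import PKA_TABLE, THREE_TO_ONE, VDW_DEFAULT, VDW_RADII

__all__ = [
    "Residue",
    "TrimerStructure",
    "ContactLabel",
    "parse_trimer",
    "shrake_rupley",
    "compute_rasa",
    "contact_areas",
    "electric_features",
    "geometric_features",
    "build_residue_descriptors",
    "build_pair_table",
    "read_asa_tsv",
    "read_contacts_tsv",
    "read_pka_tsv",
]

ResKey = tuple[str, int, str]  # (chain id, residue number, insertion code)


@dataclass(eq=False)
class Residue:
    """One amino-acid residue: identity plus heavy-atom geometry."""

    chain_id: str
    number: int
    icode: str
    resname: str
    one_letter: str
    atom_names: list[str]
    coords: np.ndarray  # (n_atoms, 3), Å
    radii: np.ndarray  # (n_atoms,), Å

    @property
    def key(self) -> ResKey:
        return (self.chain_id, self.number, self.icode)


@dataclass
class TrimerStructure:
    """Three polypeptide chains with per-residue heavy-atom coordinates."""

    chains: dict[str, list[Residue]] = field(default_factory=dict)

    @property
    def chain_ids(self) -> list[str]:
        return sorted(self.chains)

    def sequence(self, chain_id: str) -> str:
        return "".join(r.one_letter for r in self.chains[chain_id])

    def residues(self) -> list[Residue]:
        return [r for cid in self.chain_ids for r in self.chains[cid]]


@dataclass(frozen=True)
class ContactLabel:
    """Inter-chain residue pair with its atomic contact area (Å²)."""

    res_a: ResKey
    res_b: ResKey
    contact_area: float

    @property
    def is_interface(self) -> bool:
        return self.contact_area > 0


def _element_radius(element: str) -> float:
    return VDW_RADII.get(element.upper().strip(), VDW_DEFAULT)


def parse_trimer(
    source: str | Path, *, enforce_lengths: bool = True
) -> TrimerStructure:
    """Parse a trimer from PDB text or a PDB file path.

    Uses the first model only; waters, non-amino-acid heteroatoms and
    hydrogens are dropped; selenomethionine is read as methionine;
    alternate locations resolve to the highest-occupancy conformer.
    Exactly three nonempty polypeptide chains are required, and with
    ``enforce_lengths`` each chain must have 20-500 residues (the dataset
    rule for real trimers; disable for toy fixtures).
    """
    if isinstance(source, Path) or (
        "\n" not in str(source) and Path(str(source)).exists()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    parser = PDBParser(QUIET=True)
    model = next(parser.get_structure("trimer", io.StringIO(text)).get_models())

    trimer = TrimerStructure()
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            hetflag, resseq, icode = res.get_id()
            resname = res.get_resname().strip().upper()
            if hetflag not in (" ", "H_MSE"):
                continue
            if resname not in THREE_TO_ONE:
                if hetflag == " ":
                    raise ValueError(
                        f"unknown residue type {resname!r} at "
                        f"{chain.id}{resseq}{icode.strip()}"
                    )
                continue
            names, coords, radii = [], [], []
            for atom in res:  # disordered atoms yield the top-occupancy conformer
                element = (atom.element or "").upper()
                if element in ("H", "D"):
                    continue
                names.append(atom.get_name())
                coords.append(atom.get_coord())
                radii.append(_element_radius(element))
            if not names:
                continue
            residues.append(
                Residue(
                    chain_id=chain.id,
                    number=resseq,
                    icode=icode.strip(),
                    resname=resname,
                    one_letter=THREE_TO_ONE[resname],
                    atom_names=names,
                    coords=np.array(coords, dtype=float),
                    radii=np.array(radii, dtype=float),
                )
            )
        if residues:
            trimer.chains[chain.id] = residues

    n = len(trimer.chains)
    if n != 3:
        raise ValueError(f"a trimer requires 3 nonempty polypeptide chains, got {n}")
    if enforce_lengths:
        for cid, residues in trimer.chains.items():
            if not 20 <= len(residues) <= 500:
                raise ValueError(
                    f"chain {cid} has {len(residues)} residues; expected 20-500 "
                    "(pass enforce_lengths=False for toy structures)"
                )
    return trimer


def _unit_sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent accessible surface area (Å²) by sphere sampling.

    Each atom's probe-expanded sphere is covered with ``n_points``
    quasi-uniform test points; the accessible fraction is the share of
    points outside every neighbour's expanded sphere. Atoms at identical
    coordinates are rejected (degenerate geometry).
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    radii = np.asarray(radii, dtype=float).ravel()
    if len(coords) != len(radii):
        raise ValueError("coords and radii length mismatch")
    if n_points < 100:
        raise ValueError("n_points must be >= 100 for a meaningful estimate")
    if probe < 0:
        raise ValueError("probe radius must be >= 0")
    n = len(coords)
    if n == 0:
        return np.zeros(0)
    tree = cKDTree(coords)
    if tree.query_pairs(r=1e-9):
        raise ValueError("coincident atoms at identical coordinates")

    sphere = _unit_sphere_points(n_points)
    expanded = radii + probe
    max_r = expanded.max()
    areas = np.empty(n)
    neighbor_lists = tree.query_ball_tree(tree, r=2.0 * max_r)
    for i in range(n):
        ri = expanded[i]
        pts = coords[i] + ri * sphere
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbor_lists[i]:
            if j == i:
                continue
            rj = expanded[j]
            if np.dot(coords[i] - coords[j], coords[i] - coords[j]) >= (ri + rj) ** 2:
                continue
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            accessible &= d2 > rj * rj
        areas[i] = 4.0 * np.pi * ri * ri * accessible.mean()
    return areas


def compute_rasa(asa_bound: float, asa_unbound: float) -> float:
    """Relative ASA = bound / unbound; 0 (with a warning) if the residue is
    fully buried already in the isolated chain."""
    if asa_unbound < 0 or asa_bound < 0:
        raise ValueError("areas must be nonnegative")
    if asa_unbound == 0:
        warnings.warn(
            "residue fully buried in the unbound chain; RASA set to 0",
            stacklevel=2,
        )
        return 0.0
    return asa_bound / asa_unbound


def _pair_contact_area(
    ci: np.ndarray, ri: float, cj: np.ndarray, rj: float, probe: float
) -> float:
    """Mean lateral cap area of the lens where two probe-expanded spheres
    overlap; 0 when they do not."""
    R1, R2 = ri + probe, rj + probe
    d = float(np.linalg.norm(ci - cj))
    if d >= R1 + R2 or d <= 1e-12:
        return 0.0
    if d <= abs(R1 - R2):  # one sphere inside the other
        rmin = min(R1, R2)
        return 4.0 * np.pi * rmin * rmin
    h1 = np.clip(R1 - (d * d + R1 * R1 - R2 * R2) / (2.0 * d), 0.0, 2.0 * R1)
    h2 = np.clip(R2 - (d * d + R2 * R2 - R1 * R1) / (2.0 * d), 0.0, 2.0 * R2)
    return float(np.pi * (R1 * h1 + R2 * h2))  # mean of the two cap areas


def contact_areas(
    trimer: TrimerStructure, probe: float = 1.4
) -> tuple[list[ContactLabel], dict[ResKey, float], dict[ResKey, float]]:
    """All inter-chain residue-pair contact areas plus per-residue ECA/ICA.

    Returns ``(labels, eca, ica)``: one :class:`ContactLabel` per
    inter-chain residue pair with positive atomic overlap (pairs with zero
    area are omitted from the list but are non-interface by definition),
    the exterior contact area per residue (sum over atoms of other
    chains) and the interior contact area (sum over own-chain atoms of
    residues at least two positions away in the chain).
    """
    residues = trimer.residues()
    atom_res: list[int] = []
    coords_list, radii_list = [], []
    for ridx, res in enumerate(residues):
        atom_res.extend([ridx] * len(res.coords))
        coords_list.append(res.coords)
        radii_list.append(res.radii)
    coords = np.vstack(coords_list)
    radii = np.concatenate(radii_list)
    atom_res_arr = np.array(atom_res)

    chain_of = np.array(
        [trimer.chain_ids.index(res.chain_id) for res in residues]
    )
    # residues() is chain-major in chain_ids order, so positions line up
    pos_in_chain: dict[int, int] = {}
    ridx = 0
    for cid in trimer.chain_ids:
        for pos in range(len(trimer.chains[cid])):
            pos_in_chain[ridx] = pos
            ridx += 1

    eca: dict[ResKey, float] = {res.key: 0.0 for res in residues}
    ica: dict[ResKey, float] = {res.key: 0.0 for res in residues}
    pair_area: dict[tuple[int, int], float] = {}

    tree = cKDTree(coords)
    cutoff = 2.0 * (radii.max() + probe)
    for i, j in tree.query_pairs(r=cutoff):
        ri_idx, rj_idx = atom_res_arr[i], atom_res_arr[j]
        if ri_idx == rj_idx:
            continue
        area = _pair_contact_area(coords[i], radii[i], coords[j], radii[j], probe)
        if area <= 0:
            continue
        res_i, res_j = residues[ri_idx], residues[rj_idx]
        if chain_of[ri_idx] != chain_of[rj_idx]:
            eca[res_i.key] += area
            eca[res_j.key] += area
            a, b = sorted((ri_idx, rj_idx))
            pair_area[(a, b)] = pair_area.get((a, b), 0.0) + area
        else:
            if abs(pos_in_chain[ri_idx] - pos_in_chain[rj_idx]) >= 2:
                ica[res_i.key] += area
                ica[res_j.key] += area

    labels = [
        ContactLabel(res_a=residues[a].key, res_b=residues[b].key, contact_area=ar)
        for (a, b), ar in sorted(pair_area.items())
    ]
    return labels, eca, ica


def electric_features(
    residues: Sequence[Residue] | Sequence[str],
    import_table: Mapping[ResKey, tuple[float, float]] | None = None,
) -> list[tuple[float, float]]:
    """(pK1, pK2) per residue: intrinsic constants by residue type, or
    values from an imported per-residue table (missing residues fall back
    to the defaults with a warning)."""
    out = []
    for res in residues:
        if isinstance(res, str):
            one, key = res, None
        else:
            one, key = res.one_letter, res.key
        default = PKA_TABLE[one]
        if import_table is None:
            out.append(default)
        elif key is not None and key in import_table:
            out.append(import_table[key])
        else:
            warnings.warn(
                f"residue {key} missing from pKa import table; using defaults",
                stacklevel=2,
            )
            out.append(default)
    return out


def geometric_features(
    trimer: TrimerStructure,
    probe: float = 1.4,
    n_points: int = 960,
    asa_table: Mapping[ResKey, tuple[float, float]] | None = None,
    precomputed_contacts: tuple[list[ContactLabel], dict, dict] | None = None,
) -> pd.DataFrame:
    """Per-residue geometric feature table.

    Columns: ``asa_bound``, ``asa_unbound``, ``rasa``, ``eca``, ``ica``,
    ``eva``; index: (chain, residue number, insertion code). ``asa_table``
    may inject externally computed (bound, unbound) ASA per residue.
    """
    residues = trimer.residues()
    if asa_table is None:
        coords = np.vstack([r.coords for r in residues])
        radii = np.concatenate([r.radii for r in residues])
        atom_areas = shrake_rupley(coords, radii, probe=probe, n_points=n_points)
        bound: dict[ResKey, float] = {}
        k = 0
        for res in residues:
            n_at = len(res.coords)
            bound[res.key] = float(atom_areas[k : k + n_at].sum())
            k += n_at
        unbound: dict[ResKey, float] = {}
        for cid in trimer.chain_ids:
            chain_res = trimer.chains[cid]
            ccoords = np.vstack([r.coords for r in chain_res])
            cradii = np.concatenate([r.radii for r in chain_res])
            careas = shrake_rupley(ccoords, cradii, probe=probe, n_points=n_points)
            k = 0
            for res in chain_res:
                n_at = len(res.coords)
                unbound[res.key] = float(careas[k : k + n_at].sum())
                k += n_at
    else:
        bound = {key: v[0] for key, v in asa_table.items()}
        unbound = {key: v[1] for key, v in asa_table.items()}
        for res in residues:
            if res.key not in bound:
                raise ValueError(f"ASA table missing residue {res.key}")

    if precomputed_contacts is None:
        _, eca, ica = contact_areas(trimer, probe=probe)
    else:
        _, eca, ica = precomputed_contacts

    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # buried-residue RASA warnings en masse
        for res in residues:
            ab, au = bound[res.key], unbound[res.key]
            delta = max(0.0, au - ab)
            rows.append(
                {
                    "asa_bound": ab,
                    "asa_unbound": au,
                    "rasa": compute_rasa(ab, au),
                    "eca": eca.get(res.key, 0.0),
                    "ica": ica.get(res.key, 0.0),
                    "eva": max(0.0, delta - eca.get(res.key, 0.0)),
                }
            )
    index = pd.MultiIndex.from_tuples(
        [r.key for r in residues], names=["chain", "resnum", "icode"]
    )
    return pd.DataFrame(rows, index=index)


def build_residue_descriptors(
    trimer: TrimerStructure,
    scales=None,
    probe: float = 1.4,
    n_points: int = 960,
    asa_table: Mapping[ResKey, tuple[float, float]] | None = None,
    pka_table: Mapping[ResKey, tuple[float, float]] | None = None,
    precomputed_contacts: tuple[list[ContactLabel], dict, dict] | None = None,
) -> pd.DataFrame:
    """64-column per-residue descriptor table for a parsed trimer:
    57 sequence-block features, pK1/pK2, and the 5 geometric features."""
    from .encoding import sequence_feature_block
    from .pair_features import residue_descriptor_columns

    geo = geometric_features(
        trimer,
        probe=probe,
        n_points=n_points,
        asa_table=asa_table,
        precomputed_contacts=precomputed_contacts,
    )
    blocks = []
    for cid in trimer.chain_ids:
        seq = trimer.sequence(cid)
        blocks.append(sequence_feature_block(seq, scales))
    seq_block = np.vstack(blocks)

    residues = trimer.residues()
    pk = np.array(electric_features(residues, import_table=pka_table))
    geo_vals = geo[["asa_bound", "rasa", "eca", "ica", "eva"]].to_numpy()
    data = np.hstack([seq_block, pk, geo_vals])
    return pd.DataFrame(data, index=geo.index, columns=residue_descriptor_columns())


def build_pair_table(
    trimer: TrimerStructure,
    descriptors: pd.DataFrame,
    labels: Sequence[ContactLabel],
) -> pd.DataFrame:
    """All inter-chain residue pairs of the trimer as one labelled table.

    One row per pair: identification columns (interface chain ids, the two
    residue keys), the 128 feature columns (lower chain id first), and the
    ``is_interface`` label from the contact labels. Pairs are enumerated
    interface by interface (AB, AC, BC for chain ids A < B < C), residues
    in chain order within each interface.
    """
    from .pair_features import pair_columns

    interface_pairs = {
        frozenset((lbl.res_a, lbl.res_b)) for lbl in labels if lbl.is_interface
    }
    cids = trimer.chain_ids
    desc = descriptors.to_numpy()
    row_of = {key: i for i, key in enumerate(descriptors.index)}

    ident_rows, feat_rows, y = [], [], []
    for ia in range(3):
        for ib in range(ia + 1, 3):
            ca, cb = cids[ia], cids[ib]
            for res_a in trimer.chains[ca]:
                for res_b in trimer.chains[cb]:
                    ident_rows.append(
                        (ca, res_a.number, res_a.icode, cb, res_b.number, res_b.icode)
                    )
                    feat_rows.append(
                        np.concatenate(
                            [desc[row_of[res_a.key]], desc[row_of[res_b.key]]]
                        )
                    )
                    y.append(frozenset((res_a.key, res_b.key)) in interface_pairs)
    ident = pd.DataFrame(
        ident_rows,
        columns=["chain_a", "resnum_a", "icode_a", "chain_b", "resnum_b", "icode_b"],
    )
    feats = pd.DataFrame(np.array(feat_rows), columns=pair_columns())
    out = pd.concat([ident, feats], axis=1)
    out["is_interface"] = y
    return out


def _read_tsv_rows(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chain": str, "icode": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if "icode" not in df.columns:
        df["icode"] = ""
    df["icode"] = df["icode"].fillna("")
    return df


def read_asa_tsv(path: str | Path) -> dict[ResKey, tuple[float, float]]:
    """Per-residue ASA import: columns chain, resnum, asa_bound, asa_unbound
    [, icode]."""
    df = _read_tsv_rows(path, ["chain", "resnum", "asa_bound", "asa_unbound"])
    return {
        (str(r.chain), int(r.resnum), str(r.icode)): (
            float(r.asa_bound),
            float(r.asa_unbound),
        )
        for r in df.itertuples()
    }


def read_contacts_tsv(path: str | Path) -> list[ContactLabel]:
    """Per-pair contact-area import: columns chain_a, resnum_a, chain_b,
    resnum_b, contact_area [, icode_a, icode_b]."""
    df = pd.read_csv(path, sep="\t", dtype={"chain_a": str, "chain_b": str})
    required = ["chain_a", "resnum_a", "chain_b", "resnum_b", "contact_area"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in ("icode_a", "icode_b"):
        if col not in df.columns:
            df[col] = ""
        df[col] = df[col].fillna("")
    return [
        ContactLabel(
            res_a=(str(r.chain_a), int(r.resnum_a), str(r.icode_a)),
            res_b=(str(r.chain_b), int(r.resnum_b), str(r.icode_b)),
            contact_area=float(r.contact_area),
        )
        for r in df.itertuples()
    ]


def read_pka_tsv(path: str | Path) -> dict[ResKey, tuple[float, float]]:
    """Per-residue pKa import: columns chain, resnum, pk1, pk2 [, icode].
    Malformed numeric fields raise with the offending line number."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty pKa table")
    header = lines[0].rstrip("\n").split("\t")
    try:
        ic, inum = header.index("chain"), header.index("resnum")
        ip1, ip2 = header.index("pk1"), header.index("pk2")
    except ValueError as exc:
        raise ValueError(f"{path}:1: header must name chain/resnum/pk1/pk2") from exc
    i_icode = header.index("icode") if "icode" in header else None
    table: dict[ResKey, tuple[float, float]] = {}
    for lineno, ln in enumerate(lines[1:], start=2):
        if not ln.strip():
            continue
        parts = ln.split("\t")
        try:
            icode = parts[i_icode].strip() if i_icode is not None else ""
            key = (parts[ic].strip(), int(parts[inum]), icode)
            table[key] = (float(parts[ip1]), float(parts[ip2]))
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{path}:{lineno}: malformed row: {ln!r}") from exc
    return table
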