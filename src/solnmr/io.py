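"""File formats and run configuration.

TSV with a header row is the interchange format for intensity tables,
NOE pairs, RDC tables and injection heats (diffable, writable by any
spreadsheet); multi-model PDB (via gemmi) carries coordinates.  Writers
and readers round-trip losslessly so synthetic fixtures and real data
are interchangeable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .ensemble import StructureEnsemble
from .itc import InjectionSchedule, ItcExperiment
from .rdc import RdcRecord
from .relax import RelaxationSeries

__all__ = [
    "RunConfig", "read_intensity_table", "write_intensity_table",
    "read_noe_table", "write_noe_table", "read_rdc_table", "write_rdc_table",
    "read_heats_table", "write_heats_table", "read_pdb", "write_pdb",
    "write_rates_table",
]


@dataclass
class RunConfig:
    """Pipeline configuration: spectrometer, thresholds, ITC layout, seed.

    Defaults mirror the module-level defaults; every value is echoed into
    the run manifest so a run is reproducible from its outputs.
    """

    field_h1: float = 800.0
    spinlock: float = 1500.0
    noe_cut: float = 0.8
    exchange_k: float = 1.5
    iqr_k: float = 1.5
    temperature: float = 298.15
    seed: int = 0
    cell_conc: float = 50.0
    syringe_conc: float = 500.0
    n_injections: int = 20
    injection_volume: float = 2.0
    cell_volume: float = 200.0
    stages: tuple[str, ...] = ("relax", "rdc", "itc", "ensemble")

    def schedule(self) -> InjectionSchedule:
        return InjectionSchedule(
            n_injections=self.n_injections,
            injection_volume=self.injection_volume,
            cell_volume=self.cell_volume, cell_conc=self.cell_conc,
            syringe_conc=self.syringe_conc, temperature=self.temperature)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def read_intensity_table(path: str | Path) -> list[RelaxationSeries]:
    """Read a relaxation-decay TSV: one row per (residue, delay).

    Columns: residue_id, delay_s, intensity, noise_sd and optionally
    residue_name.  Duplicate (residue, delay) rows are rejected with
    their 1-based data line numbers.
    """
    df = _read_tsv(path, ["residue_id", "delay_s", "intensity", "noise_sd"])
    dup = df.duplicated(subset=["residue_id", "delay_s"], keep=False)
    if dup.any():
        lines = (df.index[dup] + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"{path}: duplicate (residue, delay) rows at lines {lines}")
    out = []
    for rid, grp in df.groupby("residue_id", sort=True):
        name = str(grp["residue_name"].iloc[0]) if "residue_name" in grp else "UNK"
        out.append(RelaxationSeries(
            residue_id=int(rid), delays=grp["delay_s"].to_numpy(),
            intensities=grp["intensity"].to_numpy(),
            noise_sd=float(grp["noise_sd"].iloc[0]), residue_name=name))
    return out


def write_intensity_table(series: list[RelaxationSeries],
                          path: str | Path) -> None:
    rows = [{"residue_id": s.residue_id, "residue_name": s.residue_name,
             "delay_s": t, "intensity": y, "noise_sd": s.noise_sd}
            for s in series for t, y in zip(s.delays, s.intensities)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_noe_table(path: str | Path) -> pd.DataFrame:
    """Saturated/reference intensity pairs: residue_id, i_sat, i_ref, noise_sd."""
    return _read_tsv(path, ["residue_id", "i_sat", "i_ref", "noise_sd"])


def write_noe_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_rdc_table(path: str | Path) -> list[RdcRecord]:
    """RDC TSV: residue_id, atom1, atom2, d_obs_hz and optional d_err_hz."""
    df = _read_tsv(path, ["residue_id", "atom1", "atom2", "d_obs_hz"])
    err = df["d_err_hz"] if "d_err_hz" in df.columns else pd.Series(0.0, index=df.index)
    return [RdcRecord(int(r.residue_id), float(r.d_obs_hz), float(e))
            for (_, r), e in zip(df.iterrows(), err)]


def write_rdc_table(records: list[RdcRecord], path: str | Path,
                    atoms: tuple[str, str] = ("N", "H")) -> None:
    pd.DataFrame([{"residue_id": r.residue_id, "atom1": atoms[0],
                   "atom2": atoms[1], "d_obs_hz": r.d_obs,
                   "d_err_hz": r.d_err} for r in records]
                 ).to_csv(path, sep="\t", index=False)


def read_heats_table(path: str | Path, sched: InjectionSchedule,
                     blank_path: str | Path | None = None) -> ItcExperiment:
    """Injection-heat TSV: injection_index, heat_ucal (blank file identical)."""
    df = _read_tsv(path, ["injection_index", "heat_ucal"])
    heats = df.sort_values("injection_index")["heat_ucal"].to_numpy()
    blank = None
    if blank_path is not None:
        bdf = _read_tsv(blank_path, ["injection_index", "heat_ucal"])
        blank = bdf.sort_values("injection_index")["heat_ucal"].to_numpy()
    return ItcExperiment(sched, heats, blank)


def write_heats_table(exp: ItcExperiment, path: str | Path) -> None:
    pd.DataFrame({"injection_index": np.arange(1, len(exp.heats) + 1),
                  "heat_ucal": exp.heats}).to_csv(path, sep="\t", index=False)


def write_rates_table(rates, labels, path: str | Path) -> None:
    """Per-residue rate summary mirroring a relaxation figure: residue_id,
    r1, r1_sd, r2, r2_sd, noe, noe_sd, label."""
    by_id = {l.residue_id: l.label for l in labels}
    pd.DataFrame([{"residue_id": r.residue_id, "r1": r.r1, "r1_sd": r.r1_sd,
                   "r2": r.r2, "r2_sd": r.r2_sd, "noe": r.noe,
                   "noe_sd": r.noe_sd, "label": by_id.get(r.residue_id, "")}
                  for r in rates]).to_csv(path, sep="\t", index=False)


def read_pdb(path: str | Path) -> StructureEnsemble:
    """Read a (multi-model) PDB file into a StructureEnsemble.

    Models must share one atom inventory; a mismatch is reported with the
    offending model number.  Alternate locations take the first conformer.
    """
    try:
        st = gemmi.read_structure(str(path))
    except RuntimeError as exc:  # truncated/corrupt records, with line info
        raise ValueError(f"{path}: PDB parse error: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    models = []
    names: dict[int, str] = {}
    for model in st:
        m: dict[int, dict[str, np.ndarray]] = {}
        for chain in model:
            for res in chain:
                rid = res.seqid.num
                names[rid] = res.name
                atoms = m.setdefault(rid, {})
                for atom in res:
                    if atom.altloc not in ("", "\0", "A"):
                        continue
                    atoms[atom.name] = np.array(
                        [atom.pos.x, atom.pos.y, atom.pos.z])
        models.append(m)
    return StructureEnsemble(models, residue_names=names)


def write_pdb(ens: StructureEnsemble, path: str | Path,
              residue_name: str = "ALA") -> None:
    """Write an ensemble as a multi-model PDB (MODEL/ENDMDL records)."""
    st = gemmi.Structure()
    st.name = "ensemble"
    for model in ens.models:
        gm = gemmi.Model(len(st) + 1)
        chain = gemmi.Chain("A")
        for rid in sorted(model):
            res = gemmi.Residue()
            res.name = ens.residue_names.get(rid, residue_name)
            res.seqid = gemmi.SeqId(rid, " ")
            for aname, xyz in model[rid].items():
                atom = gemmi.Atom()
                atom.name = aname
                atom.element = gemmi.Element(aname[:1])
                atom.pos = gemmi.Position(*xyz)
                res.add_atom(atom)
            chain.add_residue(res)
        gm.add_chain(chain)
        st.add_model(gm)
    st.setup_entities()
    doc = st.make_pdb_string()
    Path(path).write_text(doc)
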