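"""Ensemble precision: synthetic 20-model bundle -> RMSD statistics.

Builds a 30-residue, 20-model ensemble with a well-ordered core (0.3 A
per-residue scatter) and one mobile loop (residues 10-13 at 1.3 A),
superposes it and reports backbone and heavy-atom coordinate precision,
the per-residue RMSD profile and the restraint tally.
"""

from solnmr import (EnsembleSpec, RestraintTable, Selection,
                    ensemble_precision, per_residue_rmsd, simulate_ensemble,
                    tally_restraints)

scatter = tuple(1.3 if 10 <= r <= 13 else 0.3 for r in range(1, 31))
ens = simulate_ensemble(EnsembleSpec(n_models=20, n_residues=30,
                                     scatter_profile=scatter, seed=5,
                                     sidechain_scale=2.0))

bb, bb_sd = ensemble_precision(ens, Selection(atoms=("N", "CA", "C")))
heavy, heavy_sd = ensemble_precision(
    ens, Selection(atoms=("N", "CA", "C", "CB")))
print(f"backbone precision   : {bb:.2f} +/- {bb_sd:.2f} A")
print(f"heavy-atom precision : {heavy:.2f} +/- {heavy_sd:.2f} A")

profile = per_residue_rmsd(ens)
worst = max(profile, key=profile.get)
print(f"largest per-residue RMSD: {profile[worst]:.2f} A at residue {worst} "
      "(the mobile loop)")

t = RestraintTable(noe_count=1504, dihedral_phi=71, dihedral_psi=71,
                   dihedral_chi=19, hbond_count=38, rdc_count=79,
                   n_residues=87)
total, per_res = tally_restraints(t)
print(f"restraints: {total} total, {per_res:.1f} per residue")

# Heavy-atom precision exceeds backbone precision because sidechains
# scatter more; the profile maximum localises the mobile loop.
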