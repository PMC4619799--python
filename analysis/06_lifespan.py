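"""Residence times and escape probability under free coarse-grained dynamics.

Runs free Langevin dynamics (T = 0.3 eps/k_B) on structured and
unstructured 16-residue conformers, records each conformer's residence
time (last time within 2 A RMSD of its start) and assembles the escape
probability curve.
"""

import numpy as np
import pandas as pd

from common import results_dir, say

from polyqlab import descriptors as desc
from polyqlab import go_model as go
from polyqlab import lifespan as ls
from polyqlab import synthetic as syn
from polyqlab.structure import read_pdb

N_STEPS = 400_000     # 2000 tau of free dynamics per conformer


def main() -> None:
    ens_dir = results_dir("ensembles")
    out = results_dir("lifespan")
    ens = read_pdb(ens_dir / "set_n16.pdb")
    rows, pairs = [], []
    for k, c in enumerate(ens):
        has_bb = all(len(r.atoms) > 1 for r in c.residues)
        full = c if has_bb else syn.backbone_from_ca(c)
        cmap = desc.build_contact_map(full)
        model = go.build_go_model(c, cmap)
        d = desc.compute_descriptors(c)
        res = go.run_langevin(model, go.GoModelParams(seed=300 + k),
                              N_STEPS, record_every=400)
        series = ls.rmsd_series_from_frames(
            np.concatenate([[model.native_coords], res.frames]),
            np.concatenate([[0.0], res.times]))
        t_r, censored = ls.residence_time(series)
        rows.append({"id": c.id, "z_mean": round(d.z_mean, 3),
                     "volatile": d.volatile, "t_R_tau": t_r,
                     "censored": censored})
        pairs.append((t_r, censored))
    df = pd.DataFrame(rows)
    df.to_csv(out / "residence_times_n16.csv", index=False)
    curve = ls.escape_probability(pairs)
    curve.to_csv(out / "escape_probability_n16.csv")
    say(df.to_string(index=False))
    stiff = df[~df.volatile].t_R_tau
    floppy = df[df.volatile].t_R_tau
    if len(stiff) and len(floppy):
        say(f"median t_R: stiff {stiff.median():.0f} tau vs volatile "
            f"{floppy.median():.0f} tau")
    say(f"escape probability reaches {curve.P_e[-1]:.2f} by t = "
        f"{curve.times[-1]:.0f} tau")


if __name__ == "__main__":
    main()
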