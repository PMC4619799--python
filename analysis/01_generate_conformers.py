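"""Generate the synthetic conformer ensembles used by the later steps.

For each chain length a small mixed ensemble is built (helices, hairpins,
extended chains, self-avoiding coils), plus 60-residue chains with planted
trefoil and three-twist knots.  Everything is written as multi-model PDB
with a JSON sidecar of ground-truth metadata.
"""

import json

from common import results_dir, say

from polyqlab import synthetic as syn
from polyqlab.structure import Ensemble, write_pdb

LENGTHS = (16, 24, 32)
SEED = 20260928


def mixed_ensemble(n: int, seed: int) -> Ensemble:
    members = [
        syn.make_ideal("helix", n),
        syn.make_ideal("hairpin", n),
        syn.make_ideal("extended", n),
    ]
    members += [syn.make_self_avoiding_coil(n, seed + k) for k in range(4)]
    for k, c in enumerate(members):
        c.id = f"n{n}_{k:02d}_{c.id}"
    return Ensemble(members)


def main() -> None:
    out = results_dir("ensembles")
    meta = {"seed": SEED, "lengths": list(LENGTHS), "sets": {}}
    for n in LENGTHS:
        ens = mixed_ensemble(n, SEED + n)
        path = out / f"set_n{n}.pdb"
        write_pdb(ens, path)
        meta["sets"][str(n)] = {
            "file": path.name, "n_conformers": len(ens),
            "kinds": ["helix", "hairpin", "extended"] + ["coil"] * 4,
        }
        say(f"n={n}: wrote {len(ens)} conformers -> {path.name}")
    knotted = {}
    for ktype in ("3_1", "5_2"):
        c = syn.make_knotted_chain(60, ktype, (5, 5), seed=SEED)
        path = out / f"knot_{ktype}_n60.pdb"
        write_pdb(Ensemble([c]), path)
        knotted[ktype] = {
            "file": path.name,
            "planted_span_0based": list(c.planted_span),
            "planted_core_0based": list(c.planted_core),
        }
        say(f"planted {ktype} knot -> {path.name}, core {c.planted_core}")
    meta["knotted"] = knotted
    (out / "metadata.json").write_text(json.dumps(meta, indent=1))
    say("metadata ->", out / "metadata.json")


if __name__ == "__main__":
    main()
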