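"""Scale the normalized laws to absolute SI units and derive the Rall
cable-theory extensions.

Fold-range bookkeeping: the empirical size fold (2.4) propagates through
each size exponent into a theoretical fold q_T = 2.4**|c|, a theoretical
[min, max] range is anchored at the published empirical midpoints, and the
intercepts are fixed so the smallest motoneuron maps onto the appropriate
extreme of each range. The specific membrane resistivity law follows from
R_m = R * S * tanh(L)/L with the standard tanh(L)/L = 0.6, and the
composed rheobase-resistance law yields the voltage threshold amplitude.
"""

import json
from pathlib import Path

import mnrelations as mn
from mnrelations.framework import cat_framework

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    rs = mn.RelationshipSet.from_json(
        (ROOT / "relationships_normalized.json").read_text())

    s_range = mn.CAT_RANGES["S_neuron"]
    q_s = mn.CAT_SIZE_FOLD
    scaled = {}
    for prop in ("R", "I_th"):
        law = rs.size_laws[prop]
        q_t = mn.theoretical_fold(q_s, law.a)
        abs_law = mn.scale_law(law, mn.CAT_RANGES[prop], s_range)
        scaled[prop] = abs_law
        print(f"{prop}: theoretical fold q_T = {q_t:.1f}, absolute law "
              f"k = {abs_law.k:.2e}, c = {abs_law.a:.2f}")

    # published-framework reference values for the same quantities
    fw = cat_framework()
    rm_law = mn.rm_law_from_r_law(fw.law("R", "S_neuron"))
    rm_small = mn.evaluate(fw.law("R_m", "S_neuron"), s_range.min)
    composed = mn.compose(fw.law("I_th", "S_neuron"),
                          mn.invert(fw.law("R", "S_neuron")))
    vth = mn.delta_vth(composed)
    print(f"\nRall extension: R_m = {rm_law.k:.2e} * S^({rm_law.a:.2f}); "
          f"published-grid R_m at S_min = {rm_small:.2f} ohm*m^2")
    print(f"voltage threshold from composed I_th(R): "
          f"{vth * 1e3:.1f} mV (exponent {composed.a:.2f})")

    out = {
        "theoretical_folds": {
            p: mn.theoretical_fold(q_s, rs.size_laws[p].a)
            for p in rs.size_laws
        },
        "absolute_laws": {p: l.to_dict() for p, l in scaled.items()},
        "rm_law": rm_law.to_dict(),
        "delta_vth_mV": vth * 1e3,
    }
    (ROOT / "scaled_si.json").write_text(json.dumps(out, indent=2) + "\n")
    print(f"-> {ROOT / 'scaled_si.json'}")


if __name__ == "__main__":
    main()
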