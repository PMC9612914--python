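"""Sample a pool of inter-consistent motoneuron profiles.

One hundred neuron surface areas are drawn from a right-skewed (truncated
lognormal) distribution over the typical adult-cat range and expanded into
complete property profiles through the published framework; the pool is
written one motoneuron per row in SI units, sorted by size.
"""

from pathlib import Path

import mnrelations as mn

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 0


def main() -> None:
    pool = mn.generate_pool(100, seed=SEED)
    df = pool.to_frame()
    ROOT.mkdir(parents=True, exist_ok=True)
    df.to_csv(ROOT / "mn_pool.csv", index=False)

    print(f"pool of {len(pool)} motoneurons -> {ROOT / 'mn_pool.csv'}")
    for prop, unit, scale in [
        ("S_neuron", "mm^2", 1e6), ("R", "MOhm", 1e-6),
        ("I_th", "nA", 1e9), ("tau", "ms", 1e3),
        ("AHP", "ms", 1e3), ("ACV", "m/s", 1.0),
        ("dV_th", "mV", 1e3),
    ]:
        col = df[prop] * scale
        print(f"  {prop:9s} {col.min():8.2f} .. {col.max():8.2f} {unit} "
              f"(fold {col.max() / col.min():.1f})")
    small = (df.S_neuron < (df.S_neuron.min() * df.S_neuron.max()) ** 0.5
             ).mean()
    print(f"  right-skew: {small:.0%} of motoneurons below the geometric "
          "mid-size (many small, few large)")


if __name__ == "__main__":
    main()
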