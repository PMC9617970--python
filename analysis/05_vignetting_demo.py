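"""Stimulus-vignetting demonstration.

Voxels with *no* orientation tuning (orientation-pooled generative weights)
are driven by gratings windowed through a hard circular aperture. Reading
their apparent orientation preference directly off the response profile
over stimulus orientation — the readout of a classic orientation-mapping
experiment — shows the vignetting artifact: voxels whose pRF straddles the
aperture edge appear tuned to the radial orientation, while voxels well
inside the aperture show only weak orientation modulation.

Writes results/vignetting_demo.csv.
"""

from pathlib import Path

from orientmap import pipeline
from orientmap.pyramid import PyramidSpec

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    spec = PyramidSpec.for_image(128)
    demo = pipeline.run_vignetting_demo(spec)
    demo.to_csv(OUT / "vignetting_demo.csv", index=False)

    edge = demo[demo["label"] == "edge"]
    interior = demo[demo["label"] == "interior"]
    print("Apparent orientation preference of untuned (orientation-pooled) voxels:")
    print(f"  edge ring: mean deviation from radial "
          f"{edge['dev_radial'].mean():.1f} deg; "
          f"median orientation modulation {edge['modulation_depth'].median():.3f}")
    print(f"  interior ring: mean deviation from radial "
          f"{interior['dev_radial'].mean():.1f} deg; "
          f"median orientation modulation {interior['modulation_depth'].median():.4f}")
    print("  -> apparent radial preference arises only at the aperture edge")
    print(f"wrote {OUT / 'vignetting_demo.csv'}")


if __name__ == "__main__":
    main()
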