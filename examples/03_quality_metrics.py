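"""Quality metrics between the GT and progressively degraded TR arms.

SSIM and PCQI are per-pair scores (1 = identical); the Fréchet distance
compares the two arms as image *sets* through a deterministic embedding
(0 = identical distributions).  All three should worsen monotonically as
the degradation grows.
"""

from octaquant import (
    DegradationSpec,
    VascularNetworkSpec,
    degrade,
    embed,
    frechet_distance,
    generate_network,
    pcqi,
    ssim,
)

subjects = [
    generate_network(VascularNetworkSpec(image_size=128, rng_seed=s)) for s in range(10)
]
print(f"{'blur px':>8} {'mean SSIM':>10} {'mean PCQI':>10} {'Frechet':>9}")
for blur in (0.5, 1.5, 3.0):
    trs = [
        degrade(gt, DegradationSpec(blur_sigma_px=blur, rng_seed=s), geometry=geom)
        for s, (gt, geom) in enumerate(subjects)
    ]
    mean_ssim = sum(ssim(gt, tr) for (gt, _), tr in zip(subjects, trs)) / len(trs)
    mean_pcqi = sum(pcqi(gt, tr) for (gt, _), tr in zip(subjects, trs)) / len(trs)
    fid = frechet_distance(embed([g for g, _ in subjects]), embed(trs))
    print(f"{blur:8.1f} {mean_ssim:10.4f} {mean_pcqi:10.4f} {fid:9.2f}")
print("stronger blur -> lower SSIM/PCQI, larger Frechet distance")
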