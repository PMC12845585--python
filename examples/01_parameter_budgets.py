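"""Build each network variant and print its learnable-parameter budget.

SimAM adds nothing (it is parameter-free); EMA adds one grouped attention
block at the bottleneck; HWD swaps the four max-pools for wavelet blocks
with learned 1x1 heads; FEAM adds two spectral-attention blocks on the
deepest skip connections.
"""

from aphidseg import ModelConfig, build_model, count_parameters

variants = {
    "baseline UNet": ModelConfig(),
    "+ SimAM": ModelConfig(simam=True),
    "+ EMA": ModelConfig(ema=True),
    "+ HWD": ModelConfig(downsample="hwd"),
    "+ FEAM x2": ModelConfig(feam_count=2),
    "full model": ModelConfig(simam=True, ema=True, downsample="hwd", feam_count=2),
}

base = None
for name, cfg in variants.items():
    report = count_parameters(build_model(cfg, seed=0))
    base = base if base is not None else report.total
    print(f"{name:14s}  {report.millions:7.3f} M  (delta {report.total - base:+,d})")

print("\nThe delta column shows exactly what each block costs on top of the")
print("baseline; SimAM's +0 is the point of an energy-based attention.")
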