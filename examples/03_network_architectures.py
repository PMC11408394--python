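"""Build the three segmentation architectures and inspect their structure.

The 3D U-Net is the baseline; M-Net adds the class-label mask branch feeding
each encoder resolution; DM-Net additionally inserts three dilated
convolution blocks (equal dilation, filters 4F -> 2F -> F) plus one standard
block between encoder and decoder.  A forward pass confirms the softmax
output is a per-voxel probability field.
"""

import numpy as np

from pelviseg.networks import NetworkSpec, build_network
from pelviseg.preprocessing import class_vector_to_volume

shape = (64, 64, 16)
rng = np.random.default_rng(0)
image = rng.normal(size=shape + (1,)).astype(np.float32)
class_vol = class_vector_to_volume((0, 1, 1, 0), shape)

for name in ("unet3d", "mnet", "dmnet"):
    spec = NetworkSpec(name=name, input_shape=shape + (1,), n_classes=4,
                       base_filters=8, seed=0)
    net = build_network(spec)
    cv = None if name == "unet3d" else class_vol
    out = net.forward(image, class_volume=cv)
    checks = np.allclose(out.data.sum(axis=-1), 1.0, atol=1e-5)
    print(f"{name:<7} {net.parameter_count():>8,} parameters, "
          f"output {out.data.shape}, per-voxel probabilities sum to 1: {checks}")

spec = NetworkSpec(name="dmnet", input_shape=shape + (1,), n_classes=4,
                   base_filters=8)
net = build_network(spec)
print("\nDM-Net bottleneck blocks (dilation, filters):",
      [(b.dilation, b.conv.out_ch) for b in net.dcl], "+ 1 standard block")
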