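"""Declarative layer accounting for the reference ImageNet backbones.

Each function returns the exact total parameter count of the Keras
Applications variant of the architecture with its ImageNet-1000
classification head, counting every parameter including batch-norm moving
statistics (the "Total params" convention of the framework the reference
results were produced with). Conv-bias and batch-norm-scale conventions
differ per architecture and are encoded per function:

* ResNet-50: conv layers carry biases; BN has 4 params/channel.
* Xception, MobileNet-V2: convs bias-free; BN 4 params/channel.
* Inception-V3: convs bias-free; BN without a scale (gamma) term,
  3 params/channel.

These counts are pure shape arithmetic — no weights are instantiated.
"""

from __future__ import annotations

__all__ = [
    "resnet50_parameters",
    "xception_parameters",
    "inceptionv3_parameters",
    "mobilenetv2_parameters",
    "inceptionv3_output_grid",
]


def _conv(cin: int, cout: int, k: int = 3, kw: int | None = None, bias: bool = True) -> int:
    kw = k if kw is None else kw
    return k * kw * cin * cout + (cout if bias else 0)


def _bn(c: int, scale: bool = True) -> int:
    # gamma (if scaled) + beta + moving mean + moving variance
    return (4 if scale else 3) * c


def _sepconv(cin: int, cout: int, k: int = 3) -> int:
    # depthwise k*k per input channel + pointwise 1x1, both bias-free
    return k * k * cin + cin * cout


def _dense(cin: int, cout: int) -> int:
    return cin * cout + cout


def resnet50_parameters() -> int:
    total = _conv(3, 64, 7) + _bn(64)

    def bottleneck(cin: int, f: int, out: int, shortcut: bool) -> int:
        n = _conv(cin, f, 1) + _bn(f)
        n += _conv(f, f, 3) + _bn(f)
        n += _conv(f, out, 1) + _bn(out)
        if shortcut:
            n += _conv(cin, out, 1) + _bn(out)
        return n

    cin = 64
    for f, out, blocks in ((64, 256, 3), (128, 512, 4), (256, 1024, 6), (512, 2048, 3)):
        for b in range(blocks):
            total += bottleneck(cin, f, out, shortcut=(b == 0))
            cin = out
    return total + _dense(2048, 1000)


def xception_parameters() -> int:
    total = _conv(3, 32, 3, bias=False) + _bn(32)
    total += _conv(32, 64, 3, bias=False) + _bn(64)
    # entry-flow residual blocks with strided shortcut convolutions
    cin = 64
    for cout in (128, 256, 728):
        total += _sepconv(cin, cout) + _bn(cout)
        total += _sepconv(cout, cout) + _bn(cout)
        total += _conv(cin, cout, 1, bias=False) + _bn(cout)
        cin = cout
    # middle flow: 8 blocks of three 728-channel separable convolutions
    for _ in range(8):
        for _ in range(3):
            total += _sepconv(728, 728) + _bn(728)
    # exit flow
    total += _sepconv(728, 728) + _bn(728)
    total += _sepconv(728, 1024) + _bn(1024)
    total += _conv(728, 1024, 1, bias=False) + _bn(1024)
    total += _sepconv(1024, 1536) + _bn(1536)
    total += _sepconv(1536, 2048) + _bn(2048)
    return total + _dense(2048, 1000)


def _cbn(cin: int, cout: int, kh: int, kw: int | None = None) -> int:
    """Inception conv + BN unit (bias-free conv, scale-free BN)."""
    return _conv(cin, cout, kh, kw, bias=False) + _bn(cout, scale=False)


def inceptionv3_parameters() -> int:
    total = _cbn(3, 32, 3) + _cbn(32, 32, 3) + _cbn(32, 64, 3)
    total += _cbn(64, 80, 1) + _cbn(80, 192, 3)

    def block35(cin: int, pool: int) -> int:
        return (_cbn(cin, 64, 1)
                + _cbn(cin, 48, 1) + _cbn(48, 64, 5)
                + _cbn(cin, 64, 1) + _cbn(64, 96, 3) + _cbn(96, 96, 3)
                + _cbn(cin, pool, 1))

    total += block35(192, 32) + block35(256, 64) + block35(288, 64)
    # grid reduction 35 -> 17
    total += _cbn(288, 384, 3) + _cbn(288, 64, 1) + _cbn(64, 96, 3) + _cbn(96, 96, 3)

    def block17(f: int) -> int:
        cin = 768
        return (_cbn(cin, 192, 1)
                + _cbn(cin, f, 1) + _cbn(f, f, 1, 7) + _cbn(f, 192, 7, 1)
                + _cbn(cin, f, 1) + _cbn(f, f, 7, 1) + _cbn(f, f, 1, 7)
                + _cbn(f, f, 7, 1) + _cbn(f, 192, 1, 7)
                + _cbn(cin, 192, 1))

    total += block17(128) + block17(160) + block17(160) + block17(192)
    # grid reduction 17 -> 8
    total += (_cbn(768, 192, 1) + _cbn(192, 320, 3)
              + _cbn(768, 192, 1) + _cbn(192, 192, 1, 7) + _cbn(192, 192, 7, 1)
              + _cbn(192, 192, 3))

    def block8(cin: int) -> int:
        return (_cbn(cin, 320, 1)
                + _cbn(cin, 384, 1) + _cbn(384, 384, 1, 3) + _cbn(384, 384, 3, 1)
                + _cbn(cin, 448, 1) + _cbn(448, 384, 3)
                + _cbn(384, 384, 1, 3) + _cbn(384, 384, 3, 1)
                + _cbn(cin, 192, 1))

    total += block8(1280) + block8(2048)
    return total + _dense(2048, 1000)


def mobilenetv2_parameters() -> int:
    total = _conv(3, 32, 3, bias=False) + _bn(32)
    cin = 32
    # (expansion factor t, output channels c, repeats n)
    for t, c, n in ((1, 16, 1), (6, 24, 2), (6, 32, 3), (6, 64, 4),
                    (6, 96, 3), (6, 160, 3), (6, 320, 1)):
        for _ in range(n):
            mid = cin * t
            if t != 1:
                total += _conv(cin, mid, 1, bias=False) + _bn(mid)
            total += 3 * 3 * mid + _bn(mid)          # depthwise
            total += _conv(mid, c, 1, bias=False) + _bn(c)
            cin = c
    total += _conv(cin, 1280, 1, bias=False) + _bn(1280)
    return total + _dense(1280, 1000)


def inceptionv3_output_grid(size: int) -> int:
    """Spatial side of the final Inception-V3 feature map for a square input.

    The stem and reduction stages use valid (unpadded) convolutions and
    pools, so the grid does not follow a pure stride-32 rule.
    """
    def valid(s: int, k: int, stride: int) -> int:
        return (s - k) // stride + 1

    s = valid(size, 3, 2)    # stem conv /2
    s = valid(s, 3, 1)       # stem conv
    s = valid(s, 3, 2)       # maxpool (the 'same' conv before it keeps size)
    s = valid(s, 3, 1)       # 3x3 conv after 1x1
    s = valid(s, 3, 2)       # maxpool
    s = valid(s, 3, 2)       # reduction 35->17
    s = valid(s, 3, 2)       # reduction 17->8
    return s
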