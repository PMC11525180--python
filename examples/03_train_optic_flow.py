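"""Desk-scale optic-flow training of a connectome-constrained network.

Trains the four-direction detector-bank connectome jointly with the
convolutional flow decoder on drifting band patterns with analytically known
flow, and compares against a frozen-network control (decoder trained on top
of naive random biophysical parameters).  Runs in a couple of minutes.
"""

from dmnet.connectome import (SharingScheme, build_scheme_parameters,
                              scheme_from_paramset, tile)
from dmnet.fixtures import make_detector_bank, make_drifting_dataset
from dmnet.hexlattice import enumerate_hex
from dmnet.task import (Decoder, DecoderConfig, RegularizerConfig, TrainConfig,
                        train)

bank = make_detector_bank()
lattice = enumerate_hex(3)
network = tile(bank.spec, lattice)
data = make_drifting_dataset(n_train=24, n_val=12, radius=3, seed=1)
cfg = TrainConfig(iterations=300, lr_start=3e-3, lr_end=3e-4, batch=4, dt=20.0,
                  seed=0, val_every=100, regularizer=RegularizerConfig(lam=0.0))

scheme = scheme_from_paramset(network, bank.params)
decoder = Decoder(DecoderConfig(input_types=bank.spec.output_types, dropout=0.0),
                  lattice, seed=0)
result = train(network, scheme, decoder, data.train, cfg, val_dataset=data.validation)
print("joint training, validation EPE checkpoints:")
for it, e in result.val_epe:
    print(f"  iter {it:4d}: {e:.3f}")

frozen = build_scheme_parameters(bank.spec, SharingScheme.full, seed=0,
                                 network=network)
dec2 = Decoder(DecoderConfig(input_types=bank.spec.output_types, dropout=0.0),
               lattice, seed=0)
cfg_frozen = TrainConfig(**{**cfg.__dict__, "train_dmn": False})
res_f = train(network, frozen, dec2, data.train, cfg_frozen,
              val_dataset=data.validation)
print(f"frozen-network control, final validation EPE: {res_f.val_epe[-1][1]:.3f}")
# EPE is the mean Euclidean error of the per-column flow vectors (columns/s).
# The joint run drops well below its starting error; the control, whose
# recurrent dynamics carry no motion information, barely moves.
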