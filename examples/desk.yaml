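# Desk-scale benchmark: classical methods plus self-supervised training
# at 128x128, 64 views, 33 dB sinogram SNR.
image_size: 128
n_views: 64
n_detectors: 128
snr_db_levels: [33.0]
n_train: 12
n_val: 4
n_test: 6
denoiser_scales: 4
denoiser_channels: 8
learning_rate: 0.003
n_iterations: 2000
batch_size: 2
methods: [fbp, sart, sart_tv, proj2proj]
output_dir: runs/desk
seed: 0
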