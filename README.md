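# ecmprofiler

Quantitative profiling of the extracellular matrix (ECM) across the
healthy → perilesional → colorectal-carcinoma gradient.

Decellularized colon ECM changes long before tissue looks neoplastic: the
macroscopically normal mucosa within ~1 cm of a tumor ("perilesional")
already shows stiffening, collagen crosslinking, fibril linearization and
hypervascularization, while wholesale compositional dysregulation appears
only in the carcinoma itself.  `ecmprofiler` implements the quantitative
machinery needed to measure that gradient, for researchers working with
AFM nanoindentation, scanning electron micrographs, crosslink biochemistry
and label-free (LFQ) proteomics of tissue-derived ECM:

* **AFM mechanics** (`ecmprofiler.afm`) — spherical-indenter Hertz fitting
  of force-distance curves, `F = (4/3) · E/(1−ν²) · √R · δ^{3/2}`, with
  contact-point estimation by piecewise model selection and exclusion of
  the soft superficial indentation region (default first 35% of δ).
* **Stiffness statistics** (`ecmprofiler.stiffness`) — decomposition of
  Young's-modulus distributions into lognormal modes (Gaussian mixture in
  log₁₀ E, order by BIC) and the weighted-median summary
  `E = Σᵢ fᵢ·E_med,i` with per-mode median error
  `σ_med = E_med · ln10 · √(π/2) · s/√N` and total error by quadrature,
  including an instrumental relative-error floor.
* **Micrograph morphometrics** (`ecmprofiler.micrographs`) — whole-image
  fibril anisotropy from the intensity-gradient nematic tensor, automated
  fibril widths (full width at half prominence perpendicular to the local
  orientation), and capillary density / lumen width on binary masks.
* **Crosslink biochemistry** (`ecmprofiler.biochem`) — collagen from
  hydroxyproline (13.5% of collagen amino-acid composition), HP/LP
  pyridinoline summaries and per-patient folds.
* **Matrisome proteomics** (`ecmprofiler.matrisome`) — annotation of
  MaxQuant-style LFQ tables against a matrisome category table, per-protein
  ANOVA (p < 0.01), hydroxylysine intensity statistics, the collagen
  XII : VI balance and hierarchical clustering.
* **Synthetic study generator** (`ecmprofiler.synthetic`) — seeded
  generators for force volumes, fibril textures, capillary masks, LFQ
  tables and crosslink panels whose ground truth realizes the published
  gradient (stiffness ×2.5/×9.4, crosslinking ×1.5/×2, anisotropy
  0.1/0.2/0.4, capillaries 146→262 mm⁻² and 2.9→5.3 µm, fibrils
  90 ± 26 → 40 ± 8 nm), so the whole analysis is testable as closed-loop
  parameter recovery without any instrument data.

## Worked example

Simulate paired force volumes for healthy and carcinoma ECM, fit every
curve, decompose the modulus distributions and compare effective
rigidities:

```python
import numpy as np
from ecmprofiler import default_config
from ecmprofiler.synthetic import generate_force_volume
from ecmprofiler.afm import process_force_volume
from ecmprofiler.stiffness import summarize_moduli, stiffness_fold

config = default_config(seed=1)
summaries = {}
for condition in ("healthy", "crc"):
    moduli = []
    for v in range(3):
        volume = generate_force_volume(config, condition, volume_index=v)
        fits, qc = process_force_volume(volume)
        moduli.extend(f.E for f in fits if f.status == "ok")
    summaries[condition] = summarize_moduli(np.asarray(moduli), random_state=1)
```

This prints:

```
healthy: 3 modes, E = 3074 +/- 173 Pa (truth 3069 Pa)
crc: 3 modes, E = 27457 +/- 1530 Pa (truth 28849 Pa)
CRC/healthy stiffness fold: 8.93
```

Each condition's 768 fitted moduli resolve into the three configured
lognormal modes; the weighted median of mode medians recovers the true
effective rigidity within a few percent, and the carcinoma/healthy fold
lands near the configured ×9.4 stiffening.

The same loop is available from a shell.  `ecm-profiler simulate` writes a
synthetic study (force-volume JSON+TSV, TIFF micrographs with sidecar
calibration, MaxQuant-like TSVs); `afm-fit`, `modes`, `micrograph`,
`biochem` and `matrisome` analyze the artifacts; `report` runs the whole
study and emits a per-feature fold table vs healthy:

```sh
ecm-profiler simulate --seed 1 --out study/
ecm-profiler afm-fit --input study/afm/healthy_v0 --out healthy.tsv
ecm-profiler modes --fits healthy.tsv --out healthy_summary.json
ecm-profiler report --seed 1 --out report/
```

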