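dsc_code,descriptor,definition
B.T.2.3,Molecular building block nanocarrier,Drug carrier made of polymers (except protein and nucleic acid carriers that constitute an independent design solution).
E.T.2.1,Dental filling/replacement material,Nanomaterial used for the treatment of dental cavities or tooth defects.
C.T.2.3,Lipid nanocarrier,"Drug carrier made of lipids, in a broad sense."
F.T.2.1,Photothermal therapy,Generation of heat upon light stimulation.
A.T.2.2,Naked eye detection,Substances injected so that they distribute and accumulate in certain regions allowing identification (e.g. lymph tracer or near-infrared imaging).
P.T.2.3,Radiosensitive nanocarrier,Smart nanoparticle that activates when exposed to a radiation field.
K.T.1.1,Antitumoral activity,Cytotoxic effect broadly applicable for the treatment of cancer (not limited to reactive oxygen species generation).
E.T.2.2,Multimodal imaging,Substances used for simultaneous production of signals for more than one imaging technique.
B.T.1.1,Antibacterial action,Antibacterial action in a broad sense based on pharmacological means.
G.T.2.1,Radiation sensitizer,Generation of heat upon radiation for radio-therapy enhancement.
L.T.2.3,Magnetic-field targeted nanocarrier,Magnetic nanoparticle that can be guided or activated (e.g. warmed) by magnetic field exposure.
H.T.1.1,Photodynamic therapy,Reactive oxygen species generation upon photo-stimulation.
R.T.2.1,Thermotherapy,Substances that are heated up and used for thermotherapy.
B.T.2.2,MRI contrast agent,Substances for improving visibility in medical imaging based on magnetic resonance imaging (MRI).
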