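source,status,name,nhp_pattern
ASTM,Under development,"ASTM WK75607 - New Guide for Characterization of Encapsulation, Extraction, and Analysis of RNA in Lipid Nanoparticle Formulations for Drug Delivery",2.3.3s.1
ASTM,Under development,"ASTM WK67980 - New Test Method for Quantifying Poly (ethylene glycol) Coating on the Surface of Gold Nanostructured Materials Using High Performance Liquid Chromatography with Evaporative Light Scattering Detection (HPLC/ELSD)",2.3.1.0
ASTM,Under development,"ASTM WK68060 - New Test Method for Analysis of Liposomal Drug Formulations using Multidetector Asymmetrical-Flow Field-Flow Fractionation (AF4)",2.3.3s.1
European Commission,Current version,Analytical ultracentrifugation for measuring drug distribution of doxorubicin loaded liposomes in human serum,2.3.3s.1
ISO,Under development,ISO/CD TS 4958 - Nanotechnologies - Liposomes terminology,2.3.3s.1
FDA,Final,"Liposome Drug Products: Chemistry, Manufacturing, and Controls; Human Pharmacokinetics and Bioavailability; and Labeling Documentation",2.3.3s.1
EMA,Current version,Reflection paper on surface coatings: general issues for consideration regarding parenteral administration of coated nanomedicine products,2.3.0.1
EMA,Current version,Joint MHLW/EMA reflection paper on the development of block copolymer micelle medicinal products,2.3.2.1
EMA,Current version,Reflection paper on the data requirements for intravenous liposomal products developed with reference to an innovator liposomal product,2.3.3s.1
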