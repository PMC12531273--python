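database,flagged,intersection,precision
ICD10 Codes,8337,0,0.96
Cytokine Modulator Prescriptions,1762,1718,1.00
Patient Portal,3643,3483,0.97
EPR IBD Registry,4312,4288,0.97
Endoscopy Records,4327,3982,0.95
Flare Calls,7705,4428,0.87
OPCS4 Codes,1190,592,0.86
IBD Clinic Appointments,5520,4021,0.80
Calprotectin > 50,4000,3398,0.80
Clinical Letters,14984,9757,0.79
Histopathology Records,6070,5352,0.73
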