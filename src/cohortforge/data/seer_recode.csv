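kind,lo,hi,label
histology,9590,9729,Lymphoma
histology,9800,9948,Leukemia
histology,8720,8790,Melanoma of the Skin
site,C180,C189,Colon
site,C199,C209,Rectum
site,C250,C259,Pancreas
site,C340,C349,Lung and Bronchus
site,C440,C449,Other Skin
site,C500,C509,Breast
site,C530,C539,Cervix Uteri
site,C540,C549,Corpus Uteri
site,C559,C559,Uterus NOS
site,C569,C569,Ovary
site,C649,C649,Kidney
site,C670,C679,Urinary Bladder
site,C739,C739,Thyroid
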