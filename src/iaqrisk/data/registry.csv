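kind,compound,source,class_or_variant,value,units
guideline,formaldehyde,GB/T 18883-2002,iaq_standard,0.10,mg/m3
guideline,benzene,GB/T 18883-2002,iaq_standard,0.11,mg/m3
guideline,formaldehyde,OEHHA,acute,55,ug/m3
guideline,benzene,OEHHA,acute,1300,ug/m3
guideline,formaldehyde,OEHHA,chronic,9,ug/m3
guideline,benzene,OEHHA,chronic,60,ug/m3
guideline,benzene,U.S. EPA IRIS,chronic,30,ug/m3
iur,formaldehyde,U.S. EPA IRIS,default,1.30e-5,per_ug/m3
iur,benzene,U.S. EPA IRIS,default,7.8e-6,per_ug/m3
iur,benzene,U.S. EPA IRIS,alternate,2.2e-6,per_ug/m3
iur,formaldehyde,OEHHA,default,6.00e-6,per_ug/m3
iur,benzene,OEHHA,default,2.9e-5,per_ug/m3
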