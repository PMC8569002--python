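# Complication register of a 50-patient fRSA cohort (long format).
# case_index values are distinct placeholders: the source listing reports
# events without case numbers; only counts and classes are meaningful.
case_index,description,severity,months_from_surgery,attributable,treatment
3,Radial nerve palsy,minor,0,True,Complete recovery after 6 weeks
7,Axillary nerve palsy,minor,0,True,Persistent paresthesia after 12 mo
12,Radial nerve palsy,minor,0,True,Complete recovery after 6 weeks
18,Pain supercable,minor,7,True,Removal supercable
24,Impingement supercable,minor,11,True,Removal supercable
31,Pain supercable,minor,8,True,Removal supercable
9,Impingement,major,3,True,Subacromial decompression and acromioplasty
21,"Loosening humeral stem, aseptic",major,7,True,Revision
27,Shoulder dislocation,major,1,True,Open shoulder reduction
36,Periprosthetic fracture after post-operative fall,major,,False,Open reduction and internal fixation
43,Shoulder dislocation after post-operative fall,minor,,False,No further surgery at patient request
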