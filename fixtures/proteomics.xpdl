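<?xml version='1.0' encoding='UTF-8'?>
<Package xmlns="http://www.wfmc.org/2002/XPDL1.0" Id="proteomics" Name="Proteomics workflow">
  <PackageHeader>
    <XPDLVersion>1.0</XPDLVersion>
    <Vendor>labflow</Vendor>
  </PackageHeader>
  <RedefinableHeader>
    <Version>1.0</Version>
  </RedefinableHeader>
  <WorkflowProcesses>
    <WorkflowProcess Id="proteomics" Name="Proteomics workflow">
      <RedefinableHeader>
        <Version>1.0</Version>
      </RedefinableHeader>
      <Activities>
        <Activity Id="SamplePrep" Name="Sample Preparation">
          <ExtendedAttributes>
            <ExtendedAttribute Name="labflow.attribute" Value="{&quot;allowed&quot;: null, &quot;datatype&quot;: &quot;real&quot;, &quot;derivation&quot;: null, &quot;doc&quot;: &quot;ug/ul&quot;, &quot;format&quot;: null, &quot;name&quot;: &quot;Protein concentration&quot;, &quot;range&quot;: [0.0, null], &quot;required&quot;: true}"/>
            <ExtendedAttribute Name="labflow.attribute" Value="{&quot;allowed&quot;: null, &quot;datatype&quot;: &quot;string&quot;, &quot;derivation&quot;: null, &quot;doc&quot;: null, &quot;format&quot;: null, &quot;name&quot;: &quot;Buffer&quot;, &quot;range&quot;: null, &quot;required&quot;: false}"/>
            <ExtendedAttribute Name="labflow.output" Value="{&quot;artifact_type&quot;: &quot;PreparedSample&quot;, &quot;attributes&quot;: [], &quot;max&quot;: 1, &quot;min&quot;: 1}"/>
          </ExtendedAttributes>
        </Activity>
        <Activity Id="Separation" Name="Separation">
          <ExtendedAttributes>
            <ExtendedAttribute Name="labflow.attribute" Value="{&quot;allowed&quot;: [&quot;2D gel&quot;, &quot;LC&quot;], &quot;datatype&quot;: &quot;string&quot;, &quot;derivation&quot;: null, &quot;doc&quot;: null, &quot;format&quot;: null, &quot;name&quot;: &quot;Method&quot;, &quot;range&quot;: null, &quot;required&quot;: true}"/>
            <ExtendedAttribute Name="labflow.input" Value="{&quot;artifact_type&quot;: &quot;PreparedSample&quot;, &quot;attributes&quot;: [], &quot;max&quot;: 1, &quot;min&quot;: 1}"/>
            <ExtendedAttribute Name="labflow.output" Value="{&quot;artifact_type&quot;: &quot;Fraction&quot;, &quot;attributes&quot;: [{&quot;allowed&quot;: null, &quot;datatype&quot;: &quot;file&quot;, &quot;derivation&quot;: null, &quot;doc&quot;: null, &quot;format&quot;: null, &quot;name&quot;: &quot;Gel image&quot;, &quot;range&quot;: null, &quot;required&quot;: false}], &quot;max&quot;: 1, &quot;min&quot;: 1}"/>
          </ExtendedAttributes>
        </Activity>
        <Activity Id="MassSpectrometry" Name="Mass Spectrometry">
          <ExtendedAttributes>
            <ExtendedAttribute Name="labflow.attribute" Value="{&quot;allowed&quot;: null, &quot;datatype&quot;: &quot;string&quot;, &quot;derivation&quot;: null, &quot;doc&quot;: null, &quot;format&quot;: null, &quot;name&quot;: &quot;Instrument&quot;, &quot;range&quot;: null, &quot;required&quot;: false}"/>
            <ExtendedAttribute Name="labflow.attribute" Value="{&quot;allowed&quot;: null, &quot;datatype&quot;: &quot;date&quot;, &quot;derivation&quot;: null, &quot;doc&quot;: null, &quot;format&quot;: null, &quot;name&quot;: &quot;Acquisition date&quot;, &quot;range&quot;: null, &quot;required&quot;: false}"/>
            <ExtendedAttribute Name="labflow.input" Value="{&quot;artifact_type&quot;: &quot;Fraction&quot;, &quot;attributes&quot;: [], &quot;max&quot;: 1, &quot;min&quot;: 1}"/>
            <ExtendedAttribute Name="labflow.output" Value="{&quot;artifact_type&quot;: &quot;SpectraFile&quot;, &quot;attributes&quot;: [{&quot;allowed&quot;: null, &quot;datatype&quot;: &quot;file&quot;, &quot;derivation&quot;: null, &quot;doc&quot;: null, &quot;format&quot;: null, &quot;name&quot;: &quot;Raw file&quot;, &quot;range&quot;: null, &quot;required&quot;: true}], &quot;max&quot;: 1, &quot;min&quot;: 1}"/>
          </ExtendedAttributes>
        </Activity>
        <Activity Id="ProteinIdentification" Name="Protein Identification">
          <ExtendedAttributes>
            <ExtendedAttribute Name="labflow.attribute" Value="{&quot;allowed&quot;: [&quot;Mascot&quot;, &quot;SEQUEST&quot;], &quot;datatype&quot;: &quot;string&quot;, &quot;derivation&quot;: null, &quot;doc&quot;: null, &quot;format&quot;: null, &quot;name&quot;: &quot;Search engine&quot;, &quot;range&quot;: null, &quot;required&quot;: false}"/>
            <ExtendedAttribute Name="labflow.attribute" Value="{&quot;allowed&quot;: null, &quot;datatype&quot;: &quot;integer&quot;, &quot;derivation&quot;: null, &quot;doc&quot;: null, &quot;format&quot;: null, &quot;name&quot;: &quot;Proteins identified&quot;, &quot;range&quot;: [0.0, null], &quot;required&quot;: false}"/>
            <ExtendedAttribute Name="labflow.input" Value="{&quot;artifact_type&quot;: &quot;SpectraFile&quot;, &quot;attributes&quot;: [], &quot;max&quot;: 1, &quot;min&quot;: 1}"/>
          </ExtendedAttributes>
        </Activity>
      </Activities>
      <Transitions>
        <Transition Id="t0" From="SamplePrep" To="Separation"/>
        <Transition Id="t1" From="Separation" To="MassSpectrometry"/>
        <Transition Id="t2" From="MassSpectrometry" To="ProteinIdentification"/>
      </Transitions>
    </WorkflowProcess>
  </WorkflowProcesses>
</Package>
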